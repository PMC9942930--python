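"""Closed-form results for the two-state reversible switching model.

A clonal population proliferates at rate ``kx`` while individual cells switch
between two phenotypic states: State 1 -> State 2 at rate ``k1`` and
State 2 -> State 1 at rate ``k2``.  The long-run (stationary) fraction of
State-2 cells is ``f = k1/(k1+k2)`` and the dimensionless number

    Z = kx / (k1 + k2)

measures how slow switching is relative to cell division (large Z = slow,
strongly heritable states; small Z = fast, non-heritable states).

In a fluctuation test, single cells drawn from the bulk (State 2 with
probability ``f``) are expanded into colonies for a time ``t`` and the
colony-to-colony coefficient of variation of the State-2 fraction,
``CV_f^2(t)``, is measured.  This module provides the three closed-form
predictors of ``CV_f^2(t)``:

* :func:`cv2_deterministic` -- deterministic growth/switching conditioned on
  the Bernoulli initial state (exact for that reduced model, and a systematic
  underestimate of the fully stochastic process);
* :func:`cv2_independent_approx` -- moment-based formula under the closure
  that the colony fraction is independent of colony size,
  <f^2 x^2> ~ <f^2><x^2>;
* :func:`cv2_small_noise_approx` -- second-order Taylor (small-noise)
  expansion of the ratio x2/x around the mean counts.

All three equal ``(1-f)/f`` (the Bernoulli variance of the founder state) at
``t = 0``.  The independent-closure and small-noise formulas both have a
removable singularity at ``Z = 2`` where the printed limit expressions are
used instead (see :data:`Z_BRANCH_TOL`).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .exceptions import (
    DegenerateFractionError,
    DegenerateMomentError,
    DomainError,
    UndefinedFractionError,
)

__all__ = [
    "SwitchingModel",
    "MomentSummary",
    "Z_BRANCH_TOL",
    "stationary_fraction",
    "relative_speed",
    "deterministic_fraction",
    "cv2_deterministic",
    "cv2_noise_corrected",
    "cv2_independent_approx",
    "cv2_small_noise_approx",
    "cv2_from_moments",
    "fraction_second_moment_independent",
    "count_switching_topologies",
]

#: |Z - 2| below which the removable-singularity limit formulas are used.
#: Chosen to dodge catastrophic cancellation in the (Z - 2) denominators.
Z_BRANCH_TOL = 1e-8


@dataclass(frozen=True)
class SwitchingModel:
    """Two-state switching kinetics.

    Parameters
    ----------
    k1 : float
        Switching rate State 1 -> State 2, per unit time.
    k2 : float
        Switching rate State 2 -> State 1, per unit time.
    kx : float
        Cell division rate, per unit time.  With the conventional choice
        ``kx = 1`` all times are measured in average generations.
    """

    k1: float
    k2: float
    kx: float = 1.0

    def __post_init__(self) -> None:
        if self.k1 < 0 or self.k2 < 0:
            raise DomainError("switching rates k1, k2 must be nonnegative")
        if self.kx <= 0:
            raise DomainError("division rate kx must be positive")

    @property
    def rate_sum(self) -> float:
        """Relaxation rate k1 + k2 of the state-fraction ODE."""
        return self.k1 + self.k2

    @property
    def f(self) -> float:
        """Stationary State-2 fraction k1/(k1+k2)."""
        return stationary_fraction(self.k1, self.k2)

    @property
    def z(self) -> float:
        """Relative switching speed Z = kx/(k1+k2); inf if no switching."""
        return relative_speed(self)

    @classmethod
    def from_fraction(
        cls,
        f: float,
        kx: float = 1.0,
        *,
        z: float | None = None,
        rate_sum: float | None = None,
    ) -> "SwitchingModel":
        """Build a model from (f, Z) or (f, k1+k2) instead of raw rates."""
        if not 0.0 <= f <= 1.0:
            raise DomainError("f must lie in [0, 1]")
        if (z is None) == (rate_sum is None):
            raise DomainError("specify exactly one of z or rate_sum")
        if rate_sum is None:
            if z <= 0:
                raise DomainError("Z must be positive")
            rate_sum = kx / z
        if rate_sum <= 0:
            raise DomainError("k1 + k2 must be positive")
        return cls(k1=f * rate_sum, k2=(1.0 - f) * rate_sum, kx=kx)


@dataclass(frozen=True)
class MomentSummary:
    """Empirical first and second moments of colony counts (x, x2).

    ``x`` is the total number of cells in a colony and ``x2`` the number of
    State-2 cells, both at the assay time.  Angle brackets denote averages
    across colonies.
    """

    mean_total: float  #: <x>
    mean_state2: float  #: <x2>
    second_total: float  #: <x^2>
    second_state2: float  #: <x2^2>
    cross: float  #: <x2 x>

    def __post_init__(self) -> None:
        tol = 1e-9 * max(1.0, abs(self.second_total), abs(self.second_state2))
        if self.second_total < self.mean_total**2 - tol:
            raise DomainError("<x^2> < <x>^2: negative total-count variance")
        if self.second_state2 < self.mean_state2**2 - tol:
            raise DomainError("<x2^2> < <x2>^2: negative State-2 variance")
        if self.mean_state2 > self.mean_total + tol:
            raise DomainError("<x2> exceeds <x>")
        bound = math.sqrt(max(self.second_total * self.second_state2, 0.0))
        if self.cross > bound + tol:
            raise DomainError("<x2 x> violates the Cauchy-Schwarz bound")

    @classmethod
    def from_counts(cls, n_total, n_state2) -> "MomentSummary":
        """Moments of paired count samples (one entry per colony)."""
        x = np.asarray(n_total, dtype=float)
        x2 = np.asarray(n_state2, dtype=float)
        if x.shape != x2.shape or x.ndim != 1 or x.size < 1:
            raise DomainError("n_total and n_state2 must be equal-length 1-D arrays")
        return cls(
            mean_total=float(x.mean()),
            mean_state2=float(x2.mean()),
            second_total=float((x**2).mean()),
            second_state2=float((x2**2).mean()),
            cross=float((x * x2).mean()),
        )


def stationary_fraction(k1: float, k2: float) -> float:
    """Long-run fraction of State-2 cells, f = k1/(k1+k2)."""
    if k1 < 0 or k2 < 0:
        raise DomainError("switching rates must be nonnegative")
    if k1 + k2 == 0:
        raise UndefinedFractionError(
            "stationary fraction undefined when k1 + k2 = 0 (no switching)"
        )
    return k1 / (k1 + k2)


def relative_speed(model: SwitchingModel) -> float:
    """Relative switching speed Z = kx/(k1+k2).

    Returns ``inf`` when ``k1 + k2 = 0`` (irreversible / frozen-state regime):
    larger Z always means slower switching relative to division.
    """
    if model.rate_sum == 0:
        return math.inf
    return model.kx / model.rate_sum


def _check_time(t) -> np.ndarray:
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise DomainError("time t must be nonnegative")
    return t


def deterministic_fraction(model: SwitchingModel, t, initial_state: int):
    """State-2 fraction of the deterministic relaxation started in one state.

    Solves df/dt = k1 (1 - f) - k2 f from f(0) = 1 (``initial_state = 2``) or
    f(0) = 0 (``initial_state = 1``):

        f(t) = f + (1 - f) e^{-(k1+k2) t}     (start in State 2)
        f(t) = f - f e^{-(k1+k2) t}           (start in State 1)

    Under a Bernoulli(f) founder state the mixture mean is exactly ``f`` at
    every time.
    """
    t = _check_time(t)
    if initial_state not in (1, 2):
        raise DomainError("initial_state must be 1 or 2")
    f = model.f
    decay = np.exp(-model.rate_sum * t)
    if initial_state == 2:
        out = f + (1.0 - f) * decay
    else:
        out = f - f * decay
    return out if out.ndim else float(out)


def _check_fraction(model: SwitchingModel) -> float:
    f = model.f  # raises UndefinedFractionError when k1 + k2 = 0
    if f <= 0.0 or f >= 1.0:
        raise DegenerateFractionError(
            f"CV^2 of the state fraction is undefined for f = {f}"
        )
    return f


def cv2_deterministic(model: SwitchingModel, t):
    """Deterministic-model predictor of CV_f^2(t).

        CV_f^2(t) = ((1-f)/f) e^{-2 kx t / Z} = ((1-f)/f) e^{-2 (k1+k2) t}

    Only f and the relaxation rate k1+k2 enter: reparameterizations that
    preserve them (changing kx at fixed rates) leave the value unchanged.
    """
    f = _check_fraction(model)
    t = _check_time(t)
    out = (1.0 - f) / f * np.exp(-2.0 * model.rate_sum * t)
    return out if out.ndim else float(out)


def cv2_noise_corrected(model: SwitchingModel, t, cv_nc2: float, formula: str = "deterministic"):
    """A CV^2 predictor plus the technical noise floor CV_NC^2.

    Technical fluctuations measured in a noise-control experiment add to the
    biological colony-to-colony variability; in the rapid-switching limit the
    corrected prediction relaxes to ``cv_nc2`` itself.  The additive
    correction is applied to whichever predictor ``formula`` names.
    """
    if cv_nc2 < 0:
        raise DomainError("cv_nc2 must be nonnegative")
    return _PREDICTORS[formula](model, t) + cv_nc2


def _switching_bracket(z: float, kxt):
    """[2 Z e^{kx t (Z-2)/Z} - (2+Z)] / (Z-2), the kernel shared by the two
    stochastic predictors, evaluated in the cancellation-free form
    2 Z expm1(kx t (Z-2)/Z)/(Z-2) + 1 (exactly 1 at t = 0; limit 1 + 2 kx t
    at the removable Z = 2 singularity)."""
    if abs(z - 2.0) < Z_BRANCH_TOL:
        return 1.0 + 2.0 * kxt
    return 2.0 * z * np.expm1(kxt * (z - 2.0) / z) / (z - 2.0) + 1.0


def cv2_independent_approx(model: SwitchingModel, t):
    """Independent-closure predictor of CV_f^2(t).

    Uses the closure <f^2 x^2> ~ <f^2><x^2> (colony composition independent of
    colony size) together with the exact moments of the stochastic counts:

        CV_f^2(t) = ((1-f)/f) [2 Z e^{kx t (Z-2)/Z} - (2+Z)]
                              / [(2 e^{kx t} - 1)(Z - 2)]

    with the removable singularity at Z = 2 replaced by its limit

        CV_f^2(t) = ((1-f)/f) (1 + 2 kx t) / (2 e^{kx t} - 1).
    """
    f = _check_fraction(model)
    t = _check_time(t)
    z = model.z
    if not z > 0:
        raise DomainError("Z must be positive")
    kxt = model.kx * t
    pref = (1.0 - f) / f
    out = pref * _switching_bracket(z, kxt) / (2.0 * np.exp(kxt) - 1.0)
    return out if np.ndim(out) else float(out)


def cv2_small_noise_approx(model: SwitchingModel, t):
    """Small-noise (Taylor) predictor of CV_f^2(t).

    Expands the fraction x2/x to second order around the mean counts:

        CV_f^2(t) = ((1-f)/f) [2 Z e^{-2 kx t / Z} - (2+Z) e^{-kx t}] / (Z - 2)

    and at the removable Z = 2 singularity

        CV_f^2(t) = ((1-f)/f) e^{-kx t} (1 + 2 kx t).

    The expansion is accurate when fluctuations are small (late times); at
    early times it overshoots -- the curve rises from (1-f)/f with slope
    +kx (1-f)/f before decaying -- and its Z -> inf limit is
    (2 - e^{-kx t})(1-f)/f rather than the frozen-state value (1-f)/f.
    """
    f = _check_fraction(model)
    t = _check_time(t)
    z = model.z
    if not z > 0:
        raise DomainError("Z must be positive")
    kxt = model.kx * t
    pref = (1.0 - f) / f
    out = pref * np.exp(-kxt) * _switching_bracket(z, kxt)
    return out if np.ndim(out) else float(out)


_PREDICTORS = {
    "deterministic": cv2_deterministic,
    "independent": cv2_independent_approx,
    "small_noise": cv2_small_noise_approx,
}


def cv2_from_moments(m: MomentSummary) -> float:
    """Small-noise CV_f^2 from empirical count moments.

    CV_f^2 ~ Var(x2)/<x2>^2 + Var(x)/<x>^2 - 2 Cov(x2, x)/(<x2><x>).
    """
    if m.mean_total <= 0 or m.mean_state2 <= 0:
        raise DegenerateMomentError("count means must be positive")
    var2 = m.second_state2 - m.mean_state2**2
    var = m.second_total - m.mean_total**2
    cov = m.cross - m.mean_state2 * m.mean_total
    return (
        var2 / m.mean_state2**2
        + var / m.mean_total**2
        - 2.0 * cov / (m.mean_state2 * m.mean_total)
    )


def fraction_second_moment_independent(m: MomentSummary) -> float:
    """Independence-closure estimate of <f^2>, namely <x2^2>/<x^2>."""
    if m.second_total <= 0:
        raise DegenerateMomentError("<x^2> must be positive")
    return m.second_state2 / m.second_total


def count_switching_topologies(n: int) -> int:
    """Number of directed switching-network topologies on n labeled states.

    Each of the n(n-1) ordered pairs of distinct states independently has or
    lacks a transition, giving 2^(n(n-1)) topologies.  For n = 2 the four
    patterns are: reversible switching, the two irreversible directions, and
    no transitions.
    """
    if not isinstance(n, (int, np.integer)) or isinstance(n, bool):
        raise DomainError("n must be an integer")
    if n < 1:
        raise DomainError("n must be at least 1")
    return 2 ** (int(n) * (int(n) - 1))
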