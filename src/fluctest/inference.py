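"""Estimation of switching rates from fluctuation-test data.

Given colony counts at a single assay time, the mean colony fraction
estimates the stationary fraction f (the mixture mean of the process is f at
every time), and the observed colony-to-colony CV^2 -- after subtracting a
noise-control floor -- is matched against one of the closed-form predictors
to recover the relative switching speed Z.  From (f, Z) and the a priori
known division rate kx the rates follow as

    k1 + k2 = kx / Z,   k1 = f (k1+k2),   k2 = (1-f) (k1+k2),

and the transient heritabilities (mean residence times in generations) are
kx/k2 for State 2 and kx/k1 for State 1.

Identifiability is limited at both extremes.  If the corrected CV^2 is at or
below the formula's fast-switching floor, switching is effectively faster
than the assay can resolve (``fast_switching_limit``); if it reaches the
frozen-state ceiling, only a lower bound on Z can be reported
(``slow_switching_bound``).  Each predictor has its own attainable range --
the deterministic and independent-closure formulas are bounded above by
(1-f)/f, while the small-noise formula spans
(e^{-kx t}, 2 - e^{-kx t}) * (1-f)/f.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.optimize import brentq

from .analytics import SwitchingModel, _PREDICTORS
from .exceptions import DomainError
from .simulate import FluctuationDataset, dataset_summary

__all__ = [
    "FORMULAS",
    "ZInversion",
    "InferenceResult",
    "estimate_mean_fraction",
    "demographic_noise_floor",
    "invert_for_Z",
    "infer_switching_rates",
    "bootstrap_rates",
    "BootstrapResult",
]

FORMULAS = ("deterministic", "independent", "small_noise")

# log10 bracket for the bisection in Z and tolerance declaring the
# frozen-state ceiling reached (relative to (1-f)/f).
_LOG_Z_LO, _LOG_Z_HI = -6.0, 6.0
_CEILING_RTOL = 1e-9

FAST_SWITCHING_LIMIT = "fast_switching_limit"
SLOW_SWITCHING_BOUND = "slow_switching_bound"
DEGENERATE_FRACTION = "degenerate_fraction"


@dataclass(frozen=True)
class ZInversion:
    """Result of inverting a CV^2 predictor for Z.

    ``z`` is the point estimate, or a lower bound when
    ``slow_switching_bound`` is flagged, or None when ``fast_switching_limit``
    makes Z unidentifiable.
    """

    z: float | None
    flags: frozenset = frozenset()


@dataclass(frozen=True)
class InferenceResult:
    """Estimated switching kinetics from one fluctuation-test dataset."""

    f_hat: float | None
    z_hat: float | None
    k1_hat: float | None
    k2_hat: float | None
    residence_state1_generations: float | None  #: kx/k1 (mean generations in State 1)
    residence_state2_generations: float | None  #: kx/k2 (transient heritability of State 2)
    formula: str
    kx: float
    cv2_observed: float | None
    cv2_corrected: float | None
    flags: frozenset = field(default_factory=frozenset)
    n_colonies: int = 0

    @property
    def identifiable(self) -> bool:
        return not self.flags


def _predictor_fn(formula: str):
    if formula not in FORMULAS:
        raise DomainError(f"formula must be one of {FORMULAS}")
    return _PREDICTORS[formula]


def estimate_mean_fraction(ds: FluctuationDataset) -> float:
    """Unweighted mean of colony fractions: the estimator of f.

    Every colony counts as one observation regardless of its size, matching
    the ensemble-of-colonies definition of the fraction process.
    """
    if len(ds) < 2:
        raise DomainError("need at least 2 colonies")
    return float(ds.fractions.mean())


def demographic_noise_floor(ds: FluctuationDataset) -> float:
    """Within-colony sampling contribution to the observed CV^2.

    Even with instantaneous (non-heritable) switching, a colony of N cells
    shows a binomial fraction variance ~ f(1-f)/N, contributing
    (1-f)/f * <1/N> to the colony-to-colony CV^2.  For small or
    broadly-sized colonies this demographic term can dominate; it plays the
    role of a noise control computed from the dataset itself (random samples
    of the same sizes as the colonies) and can be passed as ``cv_nc2``.
    """
    f_hat = estimate_mean_fraction(ds)
    if f_hat <= 0.0 or f_hat >= 1.0:
        raise DomainError("demographic floor undefined for degenerate mean fraction")
    return float((1.0 - f_hat) / f_hat * np.mean(1.0 / ds.n_total))


def invert_for_Z(
    cv2: float,
    f: float,
    kx: float,
    t: float,
    formula: str = "independent",
    cv_nc2: float = 0.0,
) -> ZInversion:
    """Solve predictor(Z) = cv2 - cv_nc2 for the relative switching speed Z.

    The deterministic formula inverts in closed form,
    Z = -2 kx t / ln(c f/(1-f)); the other two are solved by bisection in
    log10 Z over [1e-6, 1e6], which is safe because every predictor is
    monotonically increasing in Z at fixed (f, kx, t).
    """
    if not 0.0 < f < 1.0:
        raise DomainError("f must lie strictly in (0, 1)")
    if t <= 0:
        raise DomainError("assay time t must be positive")
    if kx <= 0:
        raise DomainError("kx must be positive")
    if cv_nc2 < 0:
        raise DomainError("cv_nc2 must be nonnegative")
    predictor = _predictor_fn(formula)
    c = cv2 - cv_nc2
    if c <= 0.0:
        return ZInversion(z=None, flags=frozenset({FAST_SWITCHING_LIMIT}))

    if formula == "deterministic":
        ceiling = (1.0 - f) / f
        if c >= ceiling * (1.0 - _CEILING_RTOL):
            return ZInversion(z=10.0**_LOG_Z_HI, flags=frozenset({SLOW_SWITCHING_BOUND}))
        return ZInversion(z=-2.0 * kx * t / math.log(c * f / (1.0 - f)))

    def g(log_z: float) -> float:
        model = SwitchingModel.from_fraction(f, kx, z=10.0**log_z)
        return predictor(model, t) - c

    g_lo = g(_LOG_Z_LO)
    g_hi = g(_LOG_Z_HI)
    if g_lo >= 0.0:
        # observed variability at/below the formula's fast-switching floor
        return ZInversion(z=None, flags=frozenset({FAST_SWITCHING_LIMIT}))
    if g_hi <= 0.0:
        # at/above the frozen-state ceiling: the upper bracket is only a bound
        return ZInversion(z=10.0**_LOG_Z_HI, flags=frozenset({SLOW_SWITCHING_BOUND}))
    if formula == "independent":
        ceiling = (1.0 - f) / f
        if c >= ceiling * (1.0 - _CEILING_RTOL):
            return ZInversion(z=10.0**_LOG_Z_HI, flags=frozenset({SLOW_SWITCHING_BOUND}))
    log_z = brentq(g, _LOG_Z_LO, _LOG_Z_HI, xtol=1e-13, rtol=8.9e-16, maxiter=200)
    return ZInversion(z=10.0**log_z)


def infer_switching_rates(
    ds: FluctuationDataset,
    kx: float,
    formula: str = "independent",
    cv_nc2: float = 0.0,
) -> InferenceResult:
    """Estimate f, Z, k1, k2 and residence times from a fluctuation dataset.

    The default formula is the independent-closure predictor, the most
    accurate of the three when fluctuations are large (the informative
    regime).  ``kx`` must be known a priori (e.g., from growth curves).
    """
    _predictor_fn(formula)
    f_hat = estimate_mean_fraction(ds)
    base = InferenceResult(
        f_hat=f_hat,
        z_hat=None,
        k1_hat=None,
        k2_hat=None,
        residence_state1_generations=None,
        residence_state2_generations=None,
        formula=formula,
        kx=kx,
        cv2_observed=None,
        cv2_corrected=None,
        flags=frozenset(),
        n_colonies=len(ds),
    )
    if f_hat <= 0.0 or f_hat >= 1.0:
        return replace(base, flags=frozenset({DEGENERATE_FRACTION}))
    summary = dataset_summary(ds)
    cv2_obs = summary.cv2_fraction
    inv = invert_for_Z(cv2_obs, f_hat, kx, ds.t, formula=formula, cv_nc2=cv_nc2)
    base = replace(base, cv2_observed=cv2_obs, cv2_corrected=cv2_obs - cv_nc2, flags=inv.flags)
    if inv.z is None:
        return base
    rate_sum = kx / inv.z
    k1_hat = f_hat * rate_sum
    k2_hat = (1.0 - f_hat) * rate_sum
    return replace(
        base,
        z_hat=inv.z,
        k1_hat=k1_hat,
        k2_hat=k2_hat,
        residence_state1_generations=kx / k1_hat,
        residence_state2_generations=kx / k2_hat,
    )


@dataclass(frozen=True)
class BootstrapResult:
    """Percentile bootstrap intervals for the inferred kinetics."""

    point: InferenceResult
    ci_level: float
    k1_interval: tuple[float, float] | None
    k2_interval: tuple[float, float] | None
    residence_state1_interval: tuple[float, float] | None
    residence_state2_interval: tuple[float, float] | None
    n_boot: int
    n_flagged: int
    unreliable: bool  #: True when more than half the resamples hit a flag


def bootstrap_rates(
    ds: FluctuationDataset,
    kx: float,
    formula: str = "independent",
    cv_nc2: float = 0.0,
    n_boot: int = 500,
    seed: int = 0,
    ci_level: float = 0.95,
) -> BootstrapResult:
    """Percentile bootstrap over colonies (resampled with replacement).

    Resamples that hit an identifiability flag are counted, not silently
    dropped; if more than half are flagged the interval is declared
    unreliable.
    """
    if n_boot < 100:
        raise DomainError("n_boot must be at least 100")
    point = infer_switching_rates(ds, kx, formula=formula, cv_nc2=cv_nc2)
    rng = np.random.default_rng(np.random.SeedSequence((seed, 0xB007)))
    n = len(ds)
    k1s, k2s = [], []
    n_flagged = 0
    for _ in range(n_boot):
        idx = rng.integers(0, n, n)
        res = infer_switching_rates(
            FluctuationDataset(t=ds.t, n_total=ds.n_total[idx], n_state2=ds.n_state2[idx]),
            kx,
            formula=formula,
            cv_nc2=cv_nc2,
        )
        if res.flags:
            n_flagged += 1
        else:
            k1s.append(res.k1_hat)
            k2s.append(res.k2_hat)
    unreliable = n_flagged > n_boot // 2
    alpha = (1.0 - ci_level) / 2.0

    def interval(values: list[float]) -> tuple[float, float] | None:
        if not values:
            return None
        lo, hi = np.quantile(values, [alpha, 1.0 - alpha])
        return (float(lo), float(hi))

    k1_iv = interval(k1s)
    k2_iv = interval(k2s)
    res1_iv = (kx / k1_iv[1], kx / k1_iv[0]) if k1_iv and k1_iv[0] > 0 else None
    res2_iv = (kx / k2_iv[1], kx / k2_iv[0]) if k2_iv and k2_iv[0] > 0 else None
    return BootstrapResult(
        point=point,
        ci_level=ci_level,
        k1_interval=k1_iv,
        k2_interval=k2_iv,
        residence_state1_interval=res1_iv,
        residence_state2_interval=res2_iv,
        n_boot=n_boot,
        n_flagged=n_flagged,
        unreliable=unreliable,
    )
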