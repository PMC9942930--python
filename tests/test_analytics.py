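"""Closed-form predictors: frozen values, limits, and structural invariants."""

import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

import fluctest as ft
from fluctest.analytics import _PREDICTORS

FRACTIONS = st.floats(min_value=0.01, max_value=0.99)
ZS = st.floats(min_value=1e-2, max_value=1e3)


def model_fz(f, z, kx=1.0):
    return ft.SwitchingModel.from_fraction(f, kx, z=z)


class TestStationaryFraction:
    @pytest.mark.parametrize(
        "k1, k2, expected",
        [(1.0, 1.0, 0.5), (0.0, 5.0, 0.0), (1.0, 9.0, 0.1), (0.3, 0.0, 1.0)],
    )
    def test_values(self, k1, k2, expected):
        assert ft.stationary_fraction(k1, k2) == pytest.approx(expected, abs=1e-15)

    def test_undefined_when_no_switching(self):
        with pytest.raises(ft.UndefinedFractionError):
            ft.stationary_fraction(0.0, 0.0)

    def test_negative_rate_rejected(self):
        with pytest.raises(ft.DomainError):
            ft.stationary_fraction(-1.0, 2.0)


class TestRelativeSpeed:
    @pytest.mark.parametrize(
        "kx, k1, k2, expected",
        [(1.0, 1 / 45, 0.2, 4.5), (1.0, 0.5, 0.5, 1.0), (2.0, 0.5, 0.5, 2.0)],
    )
    def test_values(self, kx, k1, k2, expected):
        model = ft.SwitchingModel(k1=k1, k2=k2, kx=kx)
        assert ft.relative_speed(model) == pytest.approx(expected, rel=1e-12)
        assert model.z == pytest.approx(expected, rel=1e-12)

    def test_infinite_when_frozen(self):
        assert ft.relative_speed(ft.SwitchingModel(0.0, 0.0, 1.0)) == math.inf


class TestDeterministicFraction:
    def test_starts_at_initial_state(self):
        m = model_fz(0.3, 4.0)
        assert ft.deterministic_fraction(m, 0.0, 2) == pytest.approx(1.0)
        assert ft.deterministic_fraction(m, 0.0, 1) == pytest.approx(0.0)

    def test_relaxes_to_stationary(self):
        m = model_fz(0.3, 4.0)
        for state in (1, 2):
            assert ft.deterministic_fraction(m, 1e4, state) == pytest.approx(0.3, rel=1e-9)

    def test_frozen_value(self):
        # f=0.1, k1+k2=0.2, t=5, start in State 2: 0.1 + 0.9 e^{-1}
        m = ft.SwitchingModel.from_fraction(0.1, 1.0, rate_sum=0.2)
        assert ft.deterministic_fraction(m, 5.0, 2) == pytest.approx(
            0.4310914970542981, rel=1e-12
        )

    def test_negative_time_rejected(self):
        with pytest.raises(ft.DomainError):
            ft.deterministic_fraction(model_fz(0.3, 4.0), -1.0, 2)

    @given(f=FRACTIONS, z=ZS, t=st.floats(min_value=0, max_value=20))
    def test_bernoulli_mixture_mean_is_f(self, f, z, t):
        """<f(t)> = f at all times under Bernoulli(f) founder states."""
        m = model_fz(f, z)
        mean = f * ft.deterministic_fraction(m, t, 2) + (1 - f) * ft.deterministic_fraction(m, t, 1)
        assert mean == pytest.approx(f, rel=1e-12, abs=1e-14)


class TestCv2Deterministic:
    def test_bernoulli_variance_at_t0(self):
        assert ft.cv2_deterministic(model_fz(0.1, 7.0), 0.0) == pytest.approx(9.0, rel=1e-12)

    def test_frozen_value(self):
        m = ft.SwitchingModel.from_fraction(0.1, 1.0, rate_sum=0.2)
        assert ft.cv2_deterministic(m, 5.0) == pytest.approx(9.0 * math.exp(-2.0), rel=1e-12)

    def test_slow_switching_freezes_bernoulli_variance(self):
        m = ft.SwitchingModel.from_fraction(0.5, 1.0, rate_sum=1e-12)
        assert ft.cv2_deterministic(m, 10.0) == pytest.approx(1.0, rel=1e-9)

    def test_degenerate_fraction_raises(self):
        for f in (0.0, 1.0):
            with pytest.raises(ft.DegenerateFractionError):
                ft.cv2_deterministic(ft.SwitchingModel.from_fraction(f, rate_sum=1.0), 1.0)

    @given(f=FRACTIONS, rate_sum=st.floats(min_value=1e-3, max_value=10),
           kx=st.floats(min_value=0.1, max_value=10), t=st.floats(min_value=0, max_value=20))
    def test_kx_invariance(self, f, rate_sum, kx, t):
        """Only f and k1+k2 enter: kx cancels out of the exponent."""
        a = ft.SwitchingModel.from_fraction(f, 1.0, rate_sum=rate_sum)
        b = ft.SwitchingModel.from_fraction(f, kx, rate_sum=rate_sum)
        assert ft.cv2_deterministic(a, t) == pytest.approx(ft.cv2_deterministic(b, t), rel=1e-12)

    def test_exact_exponential_decay(self):
        m = ft.SwitchingModel.from_fraction(0.2, 1.0, rate_sum=0.3)
        ts = np.linspace(0, 20, 9)
        vals = np.array([ft.cv2_deterministic(m, t) for t in ts])
        expected = 4.0 * np.exp(-2 * 0.3 * ts)
        np.testing.assert_allclose(vals, expected, rtol=1e-12)


class TestNoiseCorrection:
    def test_additive_at_t0(self):
        m = model_fz(0.1, 3.0)
        assert ft.cv2_noise_corrected(m, 0.0, 0.01) == pytest.approx(9.01, rel=1e-12)

    def test_fast_switching_limit_is_noise_floor(self):
        m = ft.SwitchingModel.from_fraction(0.1, 1.0, rate_sum=1e6)
        assert ft.cv2_noise_corrected(m, 1.0, 0.009) == pytest.approx(0.009, rel=1e-9)

    def test_additivity(self):
        m = ft.SwitchingModel.from_fraction(0.1, 1.0, rate_sum=0.2)
        assert ft.cv2_noise_corrected(m, 5.0, 0.1) == pytest.approx(
            ft.cv2_deterministic(m, 5.0) + 0.1, rel=1e-12
        )

    def test_applies_to_any_formula(self):
        m = model_fz(0.1, 5.0)
        for name in ("independent", "small_noise"):
            assert ft.cv2_noise_corrected(m, 5.0, 0.05, formula=name) == pytest.approx(
                _PREDICTORS[name](m, 5.0) + 0.05, rel=1e-12
            )


class TestCv2Independent:
    def test_frozen_value(self):
        # independently verified with 30-digit arithmetic
        assert ft.cv2_independent_approx(model_fz(0.1, 5.0), 5.0) == pytest.approx(
            1.9659038831437524, rel=1e-12
        )

    def test_no_switching_limit_preserves_bernoulli_variance(self):
        assert ft.cv2_independent_approx(model_fz(0.1, 1e10), 5.0) == pytest.approx(
            9.0, rel=1e-6
        )

    def test_z_leq_zero_rejected(self):
        with pytest.raises(ft.DomainError):
            ft.SwitchingModel.from_fraction(0.1, 1.0, z=-1.0)


class TestCv2SmallNoise:
    def test_branch_value_z2(self):
        # Eq-13b-style limit: ((1-f)/f) e^{-kx t} (1 + 2 kx t) at Z = 2
        assert ft.cv2_small_noise_approx(model_fz(0.1, 2.0), 5.0) == pytest.approx(
            9.0 * math.exp(-5.0) * 11.0, rel=1e-12
        )

    def test_frozen_value(self):
        assert ft.cv2_small_noise_approx(model_fz(0.1, 5.0), 5.0) == pytest.approx(
            3.9185616101175857, rel=1e-12
        )

    def test_large_z_limit(self):
        """The Taylor closure saturates at (2 - e^{-kx t}) (1-f)/f, not (1-f)/f."""
        val = ft.cv2_small_noise_approx(model_fz(0.1, 1e10), 5.0)
        assert val == pytest.approx(9.0 * (2.0 - math.exp(-5.0)), rel=1e-6)


class TestSharedPredictorProperties:
    @given(f=FRACTIONS, z=ZS)
    def test_all_equal_bernoulli_variance_at_t0(self, f, z):
        expected = (1.0 - f) / f
        m = model_fz(f, z)
        for fn in _PREDICTORS.values():
            assert fn(m, 0.0) == pytest.approx(expected, rel=1e-10)

    @given(f=FRACTIONS)
    def test_t0_identity_near_branch(self, f):
        for z in (2.0, 2.0 + 1e-9, 2.0 - 1e-9, 2.0 + 1e-6):
            m = model_fz(f, z)
            for fn in _PREDICTORS.values():
                assert fn(m, 0.0) == pytest.approx((1 - f) / f, rel=1e-10)

    @pytest.mark.parametrize("name", ["independent", "small_noise"])
    @pytest.mark.parametrize("t", [0.5, 2.0, 5.0, 10.0])
    def test_branch_continuity_at_z2(self, name, t):
        fn = _PREDICTORS[name]
        limit = fn(model_fz(0.1, 2.0), t)
        for eps in (1e-6, -1e-6):
            assert fn(model_fz(0.1, 2.0 + eps), t) == pytest.approx(limit, rel=1e-4)

    @pytest.mark.parametrize("name", ["deterministic", "independent"])
    @pytest.mark.parametrize("t", [1.0, 5.0, 20.0])
    def test_frozen_state_limit(self, name, t):
        """Z -> inf preserves the founder Bernoulli variance (1-f)/f."""
        assert _PREDICTORS[name](model_fz(0.2, 1e10), t) == pytest.approx(4.0, rel=1e-5)

    @pytest.mark.parametrize("name", list(_PREDICTORS))
    @pytest.mark.parametrize("f", [0.05, 0.1, 0.5])
    @pytest.mark.parametrize("t", [0.5, 2.0, 5.0, 10.0])
    def test_monotone_nondecreasing_in_z(self, name, f, t):
        """Slower switching (larger Z) never decreases predicted fluctuations."""
        zs = np.logspace(-2, 3, 60)
        vals = np.array([_PREDICTORS[name](model_fz(f, z), t) for z in zs])
        assert np.all(np.diff(vals) >= -1e-12 * np.abs(vals[:-1]))

    @pytest.mark.parametrize("name", ["deterministic", "independent"])
    @pytest.mark.parametrize("f", [0.05, 0.1, 0.5])
    @pytest.mark.parametrize("z", [0.1, 1.0, 2.0, 4.5, 50.0])
    def test_nonincreasing_in_time(self, name, f, z):
        ts = np.linspace(0, 20, 80)
        vals = np.array([_PREDICTORS[name](model_fz(f, z), t) for t in ts])
        assert np.all(np.diff(vals) <= 1e-12 * np.abs(vals[:-1]))

    @pytest.mark.parametrize("f", [0.05, 0.1, 0.5])
    @pytest.mark.parametrize("z", [0.1, 1.0, 2.0, 4.5, 50.0])
    def test_small_noise_unimodal_then_decays(self, f, z):
        """The Taylor closure rises from (1-f)/f to one interior max, then decays."""
        ts = np.linspace(0, 40, 160)
        vals = np.array([ft.cv2_small_noise_approx(model_fz(f, z), t) for t in ts])
        d = np.diff(vals)
        sign_changes = np.count_nonzero(np.diff(np.sign(d[np.abs(d) > 1e-13])))
        assert sign_changes <= 1
        assert vals[-1] < vals[0]  # eventually decays below the t=0 value


class TestMoments:
    def test_hand_evaluated_cv2(self):
        m = ft.MomentSummary(
            mean_total=10.0, mean_state2=2.0, second_total=104.0,
            second_state2=5.0, cross=21.0,
        )
        assert ft.cv2_from_moments(m) == pytest.approx(0.19, rel=1e-12)
        assert ft.fraction_second_moment_independent(m) == pytest.approx(5.0 / 104.0, rel=1e-12)

    def test_perfectly_correlated_counts_have_zero_fraction_noise(self, rng):
        x = rng.integers(50, 200, 500)
        m = ft.MomentSummary.from_counts(x, (x * 0.2).astype(float))
        assert ft.cv2_from_moments(m) == pytest.approx(0.0, abs=1e-10)

    def test_independent_counts_add_cv2(self, rng):
        # exact moments of independent x, x2: covariance term vanishes
        mean, var = 100.0, 25.0
        mean2, var2 = 20.0, 9.0
        m = ft.MomentSummary(
            mean_total=mean, mean_state2=mean2,
            second_total=var + mean**2, second_state2=var2 + mean2**2,
            cross=mean * mean2,
        )
        assert ft.cv2_from_moments(m) == pytest.approx(
            var / mean**2 + var2 / mean2**2, rel=1e-12
        )

    def test_pure_state2_colonies(self):
        x = np.array([3.0, 10.0, 7.0])
        m = ft.MomentSummary.from_counts(x, x)
        assert ft.fraction_second_moment_independent(m) == pytest.approx(1.0)

    def test_invalid_moments_rejected(self):
        with pytest.raises(ft.DomainError):
            ft.MomentSummary(10.0, 2.0, 50.0, 5.0, 21.0)  # <x^2> < <x>^2
        with pytest.raises(ft.DegenerateMomentError):
            ft.cv2_from_moments(
                ft.MomentSummary(0.0, 0.0, 0.0, 0.0, 0.0)
            )


class TestTopologyCount:
    @pytest.mark.parametrize("n, expected", [(1, 1), (2, 4), (3, 64), (4, 4096)])
    def test_counts(self, n, expected):
        assert ft.count_switching_topologies(n) == expected

    def test_matches_explicit_enumeration(self):
        # brute-force: every subset of ordered pairs of distinct states
        import itertools

        for n in (2, 3):
            edges = [(i, j) for i in range(n) for j in range(n) if i != j]
            count = sum(1 for _ in itertools.product([0, 1], repeat=len(edges)))
            assert ft.count_switching_topologies(n) == count

    def test_invalid_n(self):
        with pytest.raises(ft.DomainError):
            ft.count_switching_topologies(0)
        with pytest.raises(ft.DomainError):
            ft.count_switching_topologies(2.5)
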