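"""Lambert W, the depletion-corrected consumption curve, and 1/h."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import frfit
from frfit import FRParams, TrialGeometry, lambert_w0, max_feeding_rate, predict_consumed

from conftest import rogers_fixed_point

INV_E = math.exp(-1.0)

# Newton oracle on w*e^w = 1, frozen (see conftest-style oracles):
OMEGA = 0.5671432904097838


class TestLambertW0:
    @pytest.mark.parametrize(
        "x, expected",
        [(0.0, 0.0), (math.e, 1.0), (1.0, OMEGA), (-INV_E, -1.0)],
    )
    def test_known_points(self, x, expected):
        assert lambert_w0(x) == pytest.approx(expected, abs=1e-10)

    def test_identity_on_domain(self):
        """w*exp(w) = x to 1e-10 relative across [-1/e, 10]."""
        rng = np.random.default_rng(0)
        x = rng.uniform(-INV_E, 10.0, size=1000)
        w = lambert_w0(x)
        assert np.all(np.abs(w * np.exp(w) - x) < 1e-10 * np.maximum(1.0, np.abs(x)))
        assert np.all(w >= -1.0)

    def test_agrees_with_scipy(self):
        from scipy.special import lambertw

        x = np.concatenate([np.linspace(-INV_E + 1e-9, 10, 500), [1e3, 1e6, 1e12]])
        assert np.allclose(lambert_w0(x), lambertw(x).real, rtol=1e-12, atol=1e-12)

    def test_domain_error_below_branch_point(self):
        with pytest.raises(ValueError, match="domain"):
            lambert_w0(-INV_E - 1e-3)

    def test_undershoot_is_clamped(self):
        # floating-point undershoot of -1/e must not raise
        assert lambert_w0(-INV_E - 1e-13) == pytest.approx(-1.0, abs=1e-5)


class TestPredictConsumed:
    def test_no_attacks_eats_nothing(self):
        assert predict_consumed(FRParams(0.0, 0.5), TrialGeometry(32, 1.0)) == 0.0

    def test_zero_handling_is_exponential_depletion(self):
        got = predict_consumed(FRParams(2.0, 0.0), TrialGeometry(10, 1.0))
        assert got == pytest.approx(10.0 * (1.0 - math.exp(-2.0)), rel=1e-12)

    def test_matches_frozen_bisection_value(self):
        """Bisection oracle on the implicit equation, frozen beforehand."""
        got = predict_consumed(FRParams(0.5, 0.1), TrialGeometry(32, 1.0))
        assert got == pytest.approx(5.913579655955221, abs=1e-8)

    def test_zero_density(self):
        assert predict_consumed(FRParams(1.0, 0.1), TrialGeometry(0, 1.0)) == 0.0

    @given(
        a=st.floats(1e-3, 60.0),
        h=st.floats(1e-4, 2.0),
        n0=st.integers(1, 64),
        T=st.floats(0.1, 4.0),
    )
    @settings(max_examples=300, deadline=None)
    def test_solution_satisfies_implicit_equation(self, a, h, n0, T):
        """Substituting the closed form back into the equation leaves a
        residual below 1e-9 * N_0."""
        ne = predict_consumed(FRParams(a, h), TrialGeometry(n0, T))
        resid = n0 * (1.0 - math.exp(a * (ne * h - T))) - ne
        assert abs(resid) < 1e-9 * n0
        assert 0.0 <= ne <= min(n0, T / h) + 1e-9 * n0

    def test_oracle_equivalence_on_grid(self):
        """Lambert-W closed form vs independent fixed-point solver across
        a 10x10x6 grid of (a, h, N_0)."""
        for a in np.geomspace(0.05, 50, 10):
            for h in np.geomspace(1e-3, 1.0, 10):
                for n0 in (1, 2, 4, 8, 16, 32):
                    got = predict_consumed(FRParams(a, h), TrialGeometry(n0, 1.0))
                    assert got == pytest.approx(rogers_fixed_point(a, h, n0), abs=1e-8)

    def test_monotone_in_each_argument(self):
        """Consumption rises with a, N_0, T and falls with h."""
        rng = np.random.default_rng(7)
        for _ in range(50):
            a = rng.uniform(0.1, 30)
            h = rng.uniform(0.01, 0.5)
            n0 = int(rng.integers(2, 33))
            T = rng.uniform(0.5, 2.0)
            base = predict_consumed(FRParams(a, h), TrialGeometry(n0, T))
            assert predict_consumed(FRParams(a * 1.3, h), TrialGeometry(n0, T)) >= base - 1e-9
            assert predict_consumed(FRParams(a, h * 1.3), TrialGeometry(n0, T)) <= base + 1e-9
            assert predict_consumed(FRParams(a, h), TrialGeometry(n0 + 4, T)) >= base - 1e-9
            assert predict_consumed(FRParams(a, h), TrialGeometry(n0, T * 1.3)) >= base - 1e-9

    def test_extreme_rates_do_not_overflow(self):
        # a*h*N0*exp(-a(T - h*N0)) overflows the naive form here
        ne = predict_consumed(FRParams(500.0, 0.1), TrialGeometry(32, 1.0))
        assert 9.0 < ne < 10.0 + 1e-6  # handling-limited ceiling T/h = 10


class TestParamsAndRates:
    @pytest.mark.parametrize(
        "h, expected",
        [(0.063, 15.873), (0.045, 22.222), (1.0, 1.0)],
    )
    def test_max_feeding_rate(self, h, expected):
        assert round(max_feeding_rate(h), 3) == expected

    def test_rate_requires_positive_handling(self):
        with pytest.raises(ValueError):
            max_feeding_rate(0.0)
        with pytest.raises(ValueError):
            max_feeding_rate(-0.1)

    def test_params_validation(self):
        with pytest.raises(ValueError):
            FRParams(-1.0, 0.1)
        with pytest.raises(ValueError):
            FRParams(1.0, -0.1)
        with pytest.raises(ValueError):
            TrialGeometry(-1, 1.0)
        with pytest.raises(ValueError):
            TrialGeometry(5, 0.0)

    def test_reciprocal_identity(self):
        p = FRParams(2.0, 0.125)
        assert p.max_feeding_rate * p.handling_time == pytest.approx(1.0, rel=1e-15)
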