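"""Maximum-likelihood fitting and the nonparametric bootstrap."""

import math

import numpy as np
import pandas as pd
import pytest

import frfit
from frfit import bootstrap_fr, fit_rogers
from frfit.core import _predict_consumed_arrays
from frfit.exceptions import InsufficientDataError, UnidentifiableDataError
from frfit.fitting import _GroupedTrials


def make_rounded_expectation_trials(a=2.0, h=0.08, T=1.0,
                                    densities=(1, 2, 4, 8, 16, 32), reps=3):
    """Noise-free dataset: eaten = rounded Rogers expectation per density."""
    rows = []
    for n0 in densities:
        ne = float(_predict_consumed_arrays(a, h, float(n0), T))
        for rep in range(reps):
            rows.append({"initial_density": n0, "eaten": int(round(ne)),
                         "duration": T, "replicate_id": rep})
    return pd.DataFrame(rows)


def grid_search_mle(trials, a_grid, h_grid):
    """Coarse independent grid search of the binomial Rogers likelihood."""
    n0 = trials["initial_density"].to_numpy(float)
    eaten = trials["eaten"].to_numpy(float)
    T = trials["duration"].to_numpy(float)
    best = (None, None, -np.inf)
    for a in a_grid:
        for h in h_grid:
            ne = _predict_consumed_arrays(a, h, n0, T)
            p = np.clip(ne / n0, 1e-12, 1 - 1e-12)
            ll = float(np.sum(eaten * np.log(p) + (n0 - eaten) * np.log1p(-p)))
            if ll > best[2]:
                best = (a, h, ll)
    return best


class TestFitRogers:
    def test_recovers_rounded_expectations_within_grid_band(self):
        """Fit lands inside the cell the independent grid search selects."""
        trials = make_rounded_expectation_trials(a=2.0, h=0.08)
        a_grid = np.geomspace(0.25, 16, 41)
        h_grid = np.geomspace(0.01, 0.64, 41)
        ga, gh, _ = grid_search_mle(trials, a_grid, h_grid)
        fit = fit_rogers(trials)
        # grid spacing is ~11% in log space; allow one cell either side
        assert abs(math.log(fit.params.attack_rate) - math.log(ga)) < 0.25
        assert abs(math.log(fit.params.handling_time) - math.log(gh)) < 0.25
        assert fit.converged
        assert np.isfinite(fit.loglik)

    def test_fitted_point_beats_surrounding_grid(self, brown_novel_trials):
        """The optimum dominates a 21x21 log-scale grid around itself."""
        fit = fit_rogers(brown_novel_trials)
        n0 = brown_novel_trials["initial_density"].to_numpy(float)
        eaten = brown_novel_trials["eaten"].to_numpy(float)
        T = brown_novel_trials["duration"].to_numpy(float)
        grouped = _GroupedTrials(n0, eaten, T)
        la, lh = math.log(fit.params.attack_rate), math.log(fit.params.handling_time)
        best_nll = grouped.nll(np.array([la, lh]))
        for da in np.linspace(-0.5, 0.5, 21):
            for dh in np.linspace(-0.5, 0.5, 21):
                assert grouped.nll(np.array([la + da, lh + dh])) >= best_nll - 1e-9

    def test_all_zero_consumption_is_unidentifiable(self):
        trials = pd.DataFrame({"initial_density": [1, 2, 4, 8] * 3, "eaten": 0,
                               "duration": 1.0})
        with pytest.raises(UnidentifiableDataError):
            fit_rogers(trials)

    def test_single_density_errors(self):
        trials = pd.DataFrame({"initial_density": [8] * 6,
                               "eaten": [3, 4, 5, 2, 6, 4], "duration": 1.0})
        with pytest.raises(InsufficientDataError):
            fit_rogers(trials)

    def test_deterministic_refit(self, brown_novel_trials):
        """Same data fitted twice gives a bit-identical result."""
        f1 = fit_rogers(brown_novel_trials)
        f2 = fit_rogers(brown_novel_trials)
        assert f1.params == f2.params
        assert f1.loglik == f2.loglik
        assert (f1.se_a == f2.se_a) or (math.isnan(f1.se_a) and math.isnan(f2.se_a))

    def test_permutation_invariance(self, brown_novel_trials):
        shuffled = brown_novel_trials.sample(frac=1.0, random_state=3)
        assert fit_rogers(brown_novel_trials).params == fit_rogers(shuffled).params

    def test_derived_rate_is_reciprocal(self, brown_novel_trials):
        fit = fit_rogers(brown_novel_trials)
        assert fit.max_feeding_rate * fit.params.handling_time == pytest.approx(1.0)

    def test_wald_pvalues_in_unit_interval(self, brown_novel_trials):
        fit = fit_rogers(brown_novel_trials)
        for p in (fit.p_a, fit.p_h):
            assert (0.0 <= p <= 1.0) or math.isnan(p)


class TestBootstrap:
    def test_single_replicate_degenerates_to_its_values(self, brown_novel_trials):
        boot = bootstrap_fr(brown_novel_trials, n_boot=1, seed=5)
        assert boot.ci_a[0] == boot.ci_a[1] == boot.draws[0, 0]
        assert boot.ci_h[0] == boot.ci_h[1] == boot.draws[0, 1]

    def test_seed_determinism(self, brown_novel_trials):
        b1 = bootstrap_fr(brown_novel_trials, n_boot=60, seed=9)
        b2 = bootstrap_fr(brown_novel_trials, n_boot=60, seed=9)
        assert np.array_equal(b1.draws, b2.draws)
        assert b1.ci_a == b2.ci_a and b1.ci_h == b2.ci_h
        pd.testing.assert_frame_equal(b1.band, b2.band)

    def test_different_seed_changes_draws(self, brown_novel_trials):
        b1 = bootstrap_fr(brown_novel_trials, n_boot=60, seed=9)
        b2 = bootstrap_fr(brown_novel_trials, n_boot=60, seed=10)
        assert not np.array_equal(b1.draws, b2.draws)

    def test_permutation_invariance(self, brown_novel_trials):
        shuffled = brown_novel_trials.sample(frac=1.0, random_state=4)
        b1 = bootstrap_fr(brown_novel_trials, n_boot=40, seed=2)
        b2 = bootstrap_fr(shuffled, n_boot=40, seed=2)
        assert np.array_equal(b1.draws, b2.draws)

    def test_point_estimate_inside_ci(self, brown_novel_trials):
        fit = fit_rogers(brown_novel_trials)
        boot = bootstrap_fr(brown_novel_trials, n_boot=200, seed=1, fit=fit)
        assert boot.ci_a[0] <= fit.params.attack_rate <= boot.ci_a[1]
        assert boot.ci_h[0] <= fit.params.handling_time <= boot.ci_h[1]

    def test_band_monotone_in_density(self, brown_novel_trials):
        boot = bootstrap_fr(brown_novel_trials, n_boot=100, seed=3)
        band = boot.band
        assert np.all(np.diff(band["lower"]) >= -1e-9)
        assert np.all(np.diff(band["upper"]) >= -1e-9)
        assert np.all(band["lower"] <= band["upper"] + 1e-12)

    def test_stratified_resampling_keeps_design(self, brown_novel_trials):
        boot = bootstrap_fr(brown_novel_trials, n_boot=40, seed=6, stratified=True)
        assert boot.n_redrawn == 0  # strata guarantee all densities present
        assert len(boot.draws) == 40

    def test_bca_intervals_are_finite(self, brown_novel_trials):
        boot = bootstrap_fr(brown_novel_trials, n_boot=80, seed=8, bca=True)
        assert boot.method == "bca"
        assert np.all(np.isfinite(boot.ci_a)) and np.all(np.isfinite(boot.ci_h))
        assert boot.ci_a[0] <= boot.ci_a[1]
        assert boot.ci_h[0] <= boot.ci_h[1]
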