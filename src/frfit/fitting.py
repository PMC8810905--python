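"""Maximum-likelihood estimation of Rogers' random predator equation.

Each trial's eaten count is modelled as Binomial(N_0, p) with success
probability p = N_e(a, h, N_0, T) / N_0, where N_e is the
depletion-corrected expected consumption from the Lambert-W closed form.
The likelihood is maximised over (log a, log h) — enforcing positivity —
from a fixed grid of heuristic starts, so fits are deterministic.
Standard errors come from the inverse observed information at the
optimum; Wald p-values are delta-method approximations on the natural
scale (the null of a zero rate), mirroring how starred attack rates and
handling times are conventionally reported for this model family.

Uncertainty is propagated by a nonparametric bootstrap: trial rows are
resampled with replacement to the original sample size and refitted;
percentile intervals and per-density prediction quantiles summarise the
replicate draws.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats
from scipy.special import gammaln

from .core import FRParams, _predict_consumed_arrays
from .exceptions import (
    BootstrapInstabilityError,
    ConvergenceError,
    InsufficientDataError,
    UnidentifiableDataError,
)

__all__ = ["FRFit", "BootstrapSummary", "fit_rogers", "bootstrap_fr"]

_LOG_BOUNDS = ((-12.0, 8.0), (-12.0, 5.0))  # (log a, log h)
_P_EPS = 1e-12


@dataclass(frozen=True)
class FRFit:
    """Maximum-likelihood fit of the random predator equation for one group."""

    params: FRParams
    se_a: float
    se_h: float
    p_a: float
    p_h: float
    loglik: float
    converged: bool
    n_trials: int
    group: tuple[str, str] | None = None

    @property
    def max_feeding_rate(self) -> float:
        return self.params.max_feeding_rate


@dataclass(frozen=True)
class BootstrapSummary:
    """Bootstrap replicate draws and derived uncertainty summaries.

    ``draws`` holds one (a, h) row per converged replicate; ``band`` is a
    tidy frame (density, lower, point, upper) of per-density 2.5%/97.5%
    prediction quantiles over the density grid.
    """

    n_boot: int
    draws: np.ndarray
    ci_a: tuple[float, float]
    ci_h: tuple[float, float]
    ci_max_rate: tuple[float, float]
    band: pd.DataFrame
    seed: int
    n_failed: int = 0
    n_redrawn: int = 0
    method: str = "percentile"


class _GroupedTrials:
    """Trials collapsed to unique (N_0, T) cells for fast likelihood evaluation.

    The binomial log-likelihood depends on individual counts only through
    per-cell sums plus a parameter-free combinatorial constant, so one
    Lambert-W evaluation per cell suffices per objective call.
    """

    def __init__(self, n0: np.ndarray, eaten: np.ndarray, T: np.ndarray):
        # pack (N_0, T) pairs into complex for a fast 1-D unique
        cells, inverse = np.unique(n0 + 1j * T, return_inverse=True)
        self.n0 = cells.real.copy()
        self.T = cells.imag.copy()
        k = cells.shape[0]
        self.sum_eaten = np.bincount(inverse, weights=eaten, minlength=k)
        self.n_trials_cell = np.bincount(inverse, minlength=k).astype(float)
        self.sum_offered = self.n0 * self.n_trials_cell
        self.const = float(
            np.sum(gammaln(n0 + 1) - gammaln(eaten + 1) - gammaln(n0 - eaten + 1))
        )
        self.n_rows = len(n0)

    def nll(self, theta: np.ndarray) -> float:
        a, h = math.exp(theta[0]), math.exp(theta[1])
        ne = _predict_consumed_arrays(a, h, self.n0, self.T)
        p = np.clip(ne / self.n0, _P_EPS, 1.0 - _P_EPS)
        ll = self.const + float(
            np.sum(self.sum_eaten * np.log(p) + (self.sum_offered - self.sum_eaten) * np.log1p(-p))
        )
        return -ll if np.isfinite(ll) else 1e300


def _extract_arrays(trials: pd.DataFrame):
    if "is_control" in trials.columns:
        trials = trials.loc[~trials["is_control"].astype(bool)]
    trials = trials.sort_values(["initial_density", "eaten"], kind="mergesort")
    n0 = trials["initial_density"].to_numpy(dtype=float)
    eaten = trials["eaten"].to_numpy(dtype=float)
    if "duration" in trials.columns:
        T = trials["duration"].to_numpy(dtype=float)
    else:
        T = np.ones_like(n0)
    return n0, eaten, T


def _heuristic_starts(grouped: _GroupedTrials) -> list[np.ndarray]:
    """Fixed 3x3 grid of starts around moment-style guesses.

    h0 from the high-density plateau (T / mean eaten at the largest
    density); a0 from the exponential-depletion slope at the smallest
    density with consumption.
    """
    T_bar = float(np.mean(grouped.T))
    i_hi = int(np.argmax(grouped.n0))
    mean_hi = grouped.sum_eaten[i_hi] / grouped.n_trials_cell[i_hi]
    h0 = T_bar / max(mean_hi, 0.5)

    prop = np.clip(grouped.sum_eaten / grouped.sum_offered, 0.0, 0.99)
    with_food = np.flatnonzero(prop > 0)
    if with_food.size:
        p_lo = max(prop[with_food[0]], 0.01)
        a0 = -math.log1p(-p_lo) / T_bar
    else:
        a0 = 0.1
    starts = []
    for fa in (0.25, 1.0, 4.0):
        for fh in (0.25, 1.0, 4.0):
            starts.append(np.array([math.log(a0 * fa), math.log(h0 * fh)]))
    lo = np.array([b[0] for b in _LOG_BOUNDS])
    hi = np.array([b[1] for b in _LOG_BOUNDS])
    return [np.clip(s, lo, hi) for s in starts]


def _numeric_hessian(fun, x: np.ndarray, rel_step: float = 1e-4) -> np.ndarray:
    n = len(x)
    h = rel_step * np.maximum(1.0, np.abs(x))
    H = np.empty((n, n))
    f0 = fun(x)
    for i in range(n):
        ei = np.zeros(n); ei[i] = h[i]
        H[i, i] = (fun(x + ei) - 2.0 * f0 + fun(x - ei)) / h[i] ** 2
        for j in range(i + 1, n):
            ej = np.zeros(n); ej[j] = h[j]
            H[i, j] = H[j, i] = (
                fun(x + ei + ej) - fun(x + ei - ej) - fun(x - ei + ej) + fun(x - ei - ej)
            ) / (4.0 * h[i] * h[j])
    return H


def _wald(est: float, se_log: float) -> tuple[float, float]:
    """Natural-scale SE and two-sided p via the delta method."""
    if not np.isfinite(se_log):
        return float("nan"), float("nan")
    se = est * se_log
    if se <= 0:
        return se, float("nan")
    z = est / se
    return se, float(2.0 * stats.norm.sf(abs(z)))


def _optimize(grouped: _GroupedTrials, starts) -> tuple[np.ndarray, float, bool]:
    best_x, best_f, ok = None, np.inf, False
    for x0 in starts:
        res = optimize.minimize(
            grouped.nll, x0, method="L-BFGS-B", bounds=_LOG_BOUNDS,
            options={"maxiter": 200, "ftol": 1e-12, "gtol": 1e-9},
        )
        if res.fun < best_f - 1e-12:
            best_x, best_f = res.x, float(res.fun)
            ok = bool(res.success)
        elif res.fun < best_f + 1e-12 and not ok:
            ok = bool(res.success)
    return best_x, best_f, ok


def fit_rogers(trials: pd.DataFrame, group: tuple[str, str] | None = None) -> FRFit:
    """Fit attack rate and handling time by maximum likelihood.

    Parameters
    ----------
    trials : DataFrame
        Feeding trials of one predator group with columns
        ``initial_density``, ``eaten`` and optionally ``duration``
        (default 1.0 trial unit) and ``is_control`` (controls dropped).
    group : tuple, optional
        (fish_type, novelty) key recorded on the result.

    Raises
    ------
    InsufficientDataError
        Fewer than two distinct densities.
    UnidentifiableDataError
        Zero total consumption (likelihood maximised on the a -> 0 boundary).
    ConvergenceError
        No start converged; carries the best point found.
    """
    n0, eaten, T = _extract_arrays(trials)
    if np.unique(n0).size < 2:
        raise InsufficientDataError("fitting requires >= 2 distinct prey densities")
    if np.sum(eaten) <= 0:
        raise UnidentifiableDataError(
            "total consumption is zero: attack rate is unidentifiable (boundary maximum at a = 0)"
        )

    grouped = _GroupedTrials(n0, eaten, T)
    best_x, best_f, ok = _optimize(grouped, _heuristic_starts(grouped))
    if best_x is None or not ok or not np.isfinite(best_f):
        raise ConvergenceError(
            f"optimiser failed from all starts; best objective {best_f}",
            best_point=None if best_x is None else (math.exp(best_x[0]), math.exp(best_x[1])),
        )

    a, h = math.exp(best_x[0]), math.exp(best_x[1])
    H = _numeric_hessian(grouped.nll, best_x)
    se_la = se_lh = float("nan")
    try:
        cov = np.linalg.inv(H)
        d = np.diag(cov)
        if np.all(d > 0):
            se_la, se_lh = float(np.sqrt(d[0])), float(np.sqrt(d[1]))
    except np.linalg.LinAlgError:
        pass
    se_a, p_a = _wald(a, se_la)
    se_h, p_h = _wald(h, se_lh)

    return FRFit(
        params=FRParams(attack_rate=a, handling_time=h),
        se_a=se_a, se_h=se_h, p_a=p_a, p_h=p_h,
        loglik=-best_f, converged=True, n_trials=grouped.n_rows, group=group,
    )


def _resample_ok(n0: np.ndarray, eaten: np.ndarray) -> bool:
    return np.unique(n0).size >= 2 and eaten.sum() > 0


def bootstrap_fr(
    trials: pd.DataFrame,
    n_boot: int = 2000,
    seed: int = 0,
    density_grid: np.ndarray | None = None,
    stratified: bool = False,
    bca: bool = False,
    fit: FRFit | None = None,
    max_fail_frac: float = 0.2,
) -> BootstrapSummary:
    """Nonparametric bootstrap of the random-predator fit.

    Trial rows are resampled with replacement to the original sample size
    (within density strata if ``stratified``) and refitted, warm-started
    at the point estimate.  Resamples with fewer than two distinct
    densities or zero consumption are unidentifiable and are redrawn
    (counted in ``n_redrawn``); replicates whose refit fails are dropped
    (``n_failed``).  Percentile 95% intervals are returned by default;
    ``bca=True`` applies the bias-corrected-and-accelerated adjustment.

    Raises
    ------
    BootstrapInstabilityError
        If more than ``max_fail_frac`` of replicates fail to converge.
    """
    if fit is None:
        fit = fit_rogers(trials)
    n0, eaten, T = _extract_arrays(trials)
    n = len(n0)
    if density_grid is None:
        density_grid = np.linspace(float(n0.min()), float(n0.max()), 100)
    density_grid = np.asarray(density_grid, dtype=float)
    T_grid = float(np.mean(T))

    rng = np.random.default_rng(seed)
    warm = np.array([math.log(fit.params.attack_rate), math.log(fit.params.handling_time)])
    strata = [np.flatnonzero(n0 == d) for d in np.unique(n0)] if stratified else None

    draws = np.empty((n_boot, 2))
    n_ok = n_failed = n_redrawn = 0
    for _ in range(n_boot):
        for _attempt in range(100):
            if stratified:
                idx = np.concatenate([rng.choice(s, size=s.size, replace=True) for s in strata])
            else:
                idx = rng.integers(0, n, size=n)
            if _resample_ok(n0[idx], eaten[idx]):
                break
            n_redrawn += 1
        else:
            n_failed += 1
            continue
        grouped = _GroupedTrials(n0[idx], eaten[idx], T[idx])
        res = optimize.minimize(
            grouped.nll, warm, method="L-BFGS-B", bounds=_LOG_BOUNDS,
            options={"maxiter": 200, "ftol": 1e-12, "gtol": 1e-9},
        )
        if not res.success or not np.isfinite(res.fun):
            best_x, _, ok = _optimize(grouped, _heuristic_starts(grouped))
            if not ok:
                n_failed += 1
                continue
            res_x = best_x
        else:
            res_x = res.x
        draws[n_ok] = (math.exp(res_x[0]), math.exp(res_x[1]))
        n_ok += 1

    if n_failed > max_fail_frac * n_boot:
        raise BootstrapInstabilityError(
            f"{n_failed}/{n_boot} bootstrap replicates failed to converge"
        )
    draws = draws[:n_ok]

    if bca:
        ci_a = _bca_interval(draws[:, 0], fit.params.attack_rate, n0, eaten, T, which=0)
        ci_h = _bca_interval(draws[:, 1], fit.params.handling_time, n0, eaten, T, which=1)
    else:
        ci_a = tuple(np.percentile(draws[:, 0], [2.5, 97.5]))
        ci_h = tuple(np.percentile(draws[:, 1], [2.5, 97.5]))
    ci_max_rate = tuple(np.percentile(1.0 / draws[:, 1], [2.5, 97.5]))

    preds = np.empty((n_ok, density_grid.size))
    for i in range(n_ok):
        preds[i] = _predict_consumed_arrays(draws[i, 0], draws[i, 1], density_grid, T_grid)
    lower, upper = np.percentile(preds, [2.5, 97.5], axis=0)
    point = _predict_consumed_arrays(
        fit.params.attack_rate, fit.params.handling_time, density_grid, T_grid
    )
    band = pd.DataFrame(
        {"density": density_grid, "lower": lower, "point": point, "upper": upper}
    )

    return BootstrapSummary(
        n_boot=n_boot, draws=draws,
        ci_a=(float(ci_a[0]), float(ci_a[1])),
        ci_h=(float(ci_h[0]), float(ci_h[1])),
        ci_max_rate=(float(ci_max_rate[0]), float(ci_max_rate[1])),
        band=band, seed=seed, n_failed=n_failed, n_redrawn=n_redrawn,
        method="bca" if bca else "percentile",
    )


def _bca_interval(draws: np.ndarray, theta_hat: float, n0, eaten, T, which: int,
                  level: float = 0.95) -> tuple[float, float]:
    """Bias-corrected and accelerated percentile interval.

    Acceleration from the jackknife over trial rows; falls back to the
    plain percentile interval when the draws are degenerate.
    """
    if np.allclose(draws, draws[0]):
        return float(draws[0]), float(draws[0])
    prop_less = np.mean(draws < theta_hat)
    if prop_less in (0.0, 1.0):
        return tuple(np.percentile(draws, [2.5, 97.5]))
    z0 = stats.norm.ppf(prop_less)

    n = len(n0)
    jack = np.empty(n)
    for i in range(n):
        keep = np.arange(n) != i
        try:
            f = fit_rogers(pd.DataFrame({
                "initial_density": n0[keep], "eaten": eaten[keep], "duration": T[keep],
            }))
            jack[i] = f.params.attack_rate if which == 0 else f.params.handling_time
        except Exception:
            jack[i] = theta_hat
    jm = jack.mean()
    num = np.sum((jm - jack) ** 3)
    den = 6.0 * np.sum((jm - jack) ** 2) ** 1.5
    acc = num / den if den > 0 else 0.0

    alpha = (1.0 - level) / 2.0
    lo_hi = []
    for q in (alpha, 1.0 - alpha):
        zq = stats.norm.ppf(q)
        adj = stats.norm.cdf(z0 + (z0 + zq) / (1.0 - acc * (z0 + zq)))
        lo_hi.append(float(np.percentile(draws, 100.0 * adj)))
    return lo_hi[0], lo_hi[1]
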