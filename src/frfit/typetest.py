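"""Functional-response type classification.

The shape of a functional response is diagnosed from the density
dependence of the *proportion* of prey consumed: a binomial logistic
regression of (eaten, surviving) on initial prey density.  A
significantly negative first-order (linear density) term indicates a
hyperbolic Type II response; a significantly positive first-order term
followed by a significantly negative second-order (quadratic) term
indicates a sigmoidal Type III response.  Anything else is reported as
inconclusive.

The linear-only model is fitted first; the quadratic model is fitted
only when the linear term is significantly positive, matching the
sequential wording of the decision rule.  Counts are modelled as grouped
binomial successes/failures rather than pre-computed proportions so that
density-1 trials (eaten 0 or 1) contribute exactly.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .exceptions import (
    CompleteSeparationError,
    DegenerateDataError,
    InsufficientDataError,
)

__all__ = ["TypeTestResult", "classify_fr_type"]

TYPE_II = "type_II"
TYPE_III = "type_III"
INCONCLUSIVE = "inconclusive"


@dataclass(frozen=True)
class TypeTestResult:
    """Outcome of the logistic curve-shape test for one predator group.

    ``first_order``/``second_order`` are the density and squared-density
    coefficients on the logit scale (``second_order`` is None when only
    the linear model was fitted); ``label`` is one of ``type_II``,
    ``type_III`` or ``inconclusive``.
    """

    first_order: float
    p_first: float
    second_order: float | None
    p_second: float | None
    label: str
    n_trials: int
    alpha: float


def _fit_binomial(eaten: np.ndarray, offered: np.ndarray, design: np.ndarray):
    endog = np.column_stack([eaten, offered - eaten])
    model = sm.GLM(endog, design, family=sm.families.Binomial())
    try:
        res = model.fit(maxiter=200)
    except Exception as exc:  # statsmodels raises PerfectSeparationError and kin
        raise CompleteSeparationError(f"binomial logistic fit failed: {exc}") from exc
    if not np.all(np.isfinite(res.params)) or not np.all(np.isfinite(res.bse)):
        raise CompleteSeparationError("binomial logistic fit returned non-finite coefficients")
    return res


def classify_fr_type(trials: pd.DataFrame, alpha: float = 0.05) -> TypeTestResult:
    """Classify the functional-response type of one predator group.

    Parameters
    ----------
    trials : DataFrame
        Feeding trials of a single group, with columns
        ``initial_density`` and ``eaten`` (control rows, if present under
        an ``is_control`` column, are ignored).
    alpha : float
        Two-sided significance level for the sign rules.

    Returns
    -------
    TypeTestResult

    Raises
    ------
    InsufficientDataError
        Fewer than two distinct densities.
    DegenerateDataError
        Zero consumption in every trial, or total consumption in every
        trial (the logit is unbounded; no shape information).
    """
    if "is_control" in trials.columns:
        trials = trials.loc[~trials["is_control"].astype(bool)]
    # canonical row order: the test is invariant to input permutation
    trials = trials.sort_values(["initial_density", "eaten"], kind="mergesort")
    n0 = trials["initial_density"].to_numpy(dtype=float)
    eaten = trials["eaten"].to_numpy(dtype=float)

    if np.unique(n0).size < 2:
        raise InsufficientDataError("type classification requires >= 2 distinct prey densities")
    if np.all(eaten == 0):
        raise DegenerateDataError("no prey were consumed in any trial")
    if np.all(eaten == n0):
        raise DegenerateDataError("all prey were consumed in every trial")

    n = len(trials)
    linear = _fit_binomial(eaten, n0, sm.add_constant(n0))
    b1, p1 = float(linear.params[1]), float(linear.pvalues[1])

    if b1 < 0 and p1 < alpha:
        return TypeTestResult(b1, p1, None, None, TYPE_II, n, alpha)

    if b1 > 0 and p1 < alpha:
        design = np.column_stack([np.ones_like(n0), n0, n0**2])
        quad = _fit_binomial(eaten, n0, design)
        qb1, qp1 = float(quad.params[1]), float(quad.pvalues[1])
        qb2, qp2 = float(quad.params[2]), float(quad.pvalues[2])
        if qb1 > 0 and qp1 < alpha and qb2 < 0 and qp2 < alpha:
            return TypeTestResult(qb1, qp1, qb2, qp2, TYPE_III, n, alpha)
        return TypeTestResult(qb1, qp1, qb2, qp2, INCONCLUSIVE, n, alpha)

    return TypeTestResult(b1, p1, None, None, INCONCLUSIVE, n, alpha)
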