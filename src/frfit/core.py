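"""Deterministic core of the functional-response model.

Rogers' random predator equation describes the number of prey eaten
``N_e`` in a closed arena over a trial of length ``T`` when consumed prey
are not replaced::

    N_e = N_0 * (1 - exp(a * (N_e * h - T)))

with attack rate ``a`` (search efficiency) and handling time ``h`` (time
spent per captured prey, during which no searching occurs).  The equation
is implicit in ``N_e``; on the principal branch of the Lambert W function
it has the closed-form solution

    N_e = N_0 - W0(a*h*N_0 * exp(-a*(T - h*N_0))) / (a*h).

Time is trial-normalised throughout: one trial duration (the 4-h arena
trial) is 1.0 time unit, so ``h`` is in trial-durations per prey item and
``1/h`` is the maximum feeding rate in prey per trial.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "FRParams",
    "TrialGeometry",
    "lambert_w0",
    "predict_consumed",
    "max_feeding_rate",
]

_INV_E = np.exp(-1.0)


@dataclass(frozen=True)
class FRParams:
    """Type II functional-response parameters.

    Attributes
    ----------
    attack_rate : float
        Instantaneous search-efficiency coefficient ``a`` (per unit prey
        density per trial duration). Must be positive for a fitted result.
    handling_time : float
        Time cost ``h`` per prey item, in trial durations. Non-negative.
    """

    attack_rate: float
    handling_time: float

    def __post_init__(self) -> None:
        if not np.isfinite(self.attack_rate) or self.attack_rate < 0:
            raise ValueError(f"attack_rate must be finite and >= 0, got {self.attack_rate}")
        if not np.isfinite(self.handling_time) or self.handling_time < 0:
            raise ValueError(f"handling_time must be finite and >= 0, got {self.handling_time}")

    @property
    def max_feeding_rate(self) -> float:
        """Maximum feeding rate ``1/h`` in prey per trial duration."""
        return max_feeding_rate(self.handling_time)


@dataclass(frozen=True)
class TrialGeometry:
    """Arena geometry of a single feeding trial.

    ``initial_density`` is the count of prey offered (N_0); ``duration``
    is the trial length T in trial-duration units (1.0 = one 4-h trial).
    """

    initial_density: int
    duration: float = 1.0

    def __post_init__(self) -> None:
        if self.initial_density < 0 or int(self.initial_density) != self.initial_density:
            raise ValueError(f"initial_density must be a non-negative integer, got {self.initial_density}")
        if not self.duration > 0:
            raise ValueError(f"duration must be positive, got {self.duration}")


def lambert_w0(x, tol: float = 1e-12):
    """Principal branch of the Lambert W function, ``w * exp(w) = x``.

    Halley iteration from a series-based initial guess.  Defined for
    ``x >= -1/e``; arguments that undershoot ``-1/e`` by no more than a
    small floating-point tolerance are clamped to the branch point.

    Parameters
    ----------
    x : float or array_like
        Argument(s), each >= -1/e (up to clamping tolerance).
    tol : float
        Relative tolerance on the defining identity.

    Returns
    -------
    float or ndarray
        ``W0(x)``, satisfying ``w >= -1``.
    """
    x_arr = np.asarray(x, dtype=float)
    scalar = x_arr.ndim == 0
    z = np.atleast_1d(x_arr).copy()

    if np.any(z < -_INV_E - 1e-9):
        raise ValueError("lambert_w0 domain error: argument < -1/e")
    # floating point can undershoot the branch point; clamp
    np.clip(z, -_INV_E, None, out=z)

    w = np.empty_like(z)
    # series about the branch point: W0(z) ~ -1 + sqrt(2(1 + e z)) for z near -1/e
    p = 1.0 + np.e * z
    near = p < 0.5
    w[near] = -1.0 + np.sqrt(np.maximum(2.0 * p[near], 0.0))
    # asymptotic guess for large z, log1p guess in between
    big = z > np.e
    mid = ~near & ~big
    with np.errstate(divide="ignore", invalid="ignore"):
        lz = np.log(np.where(big, z, 1.0))
        w[big] = lz[big] - np.log(np.maximum(lz[big], 1e-300))
    w[mid] = np.log1p(z[mid])

    active = p > 0  # at the branch point itself, w = -1 exactly
    w[~active] = -1.0
    for _ in range(50):
        if not np.any(active):
            break
        wa, za = w[active], z[active]
        ew = np.exp(wa)
        f = wa * ew - za
        # Halley step
        denom = ew * (wa + 1.0) - (wa + 2.0) * f / (2.0 * wa + 2.0)
        step = f / denom
        w[active] = wa - step
        still = np.abs(f) > tol * np.maximum(1.0, np.abs(za))
        idx = np.flatnonzero(active)
        active[idx[~still]] = False

    np.clip(w, -1.0, None, out=w)
    return float(w[0]) if scalar else w.reshape(x_arr.shape)


def _w0_exp(lx: np.ndarray) -> np.ndarray:
    """``W0(exp(lx))`` for real ``lx`` (strictly positive argument).

    Newton iteration on ``f(w) = w + log(w) - lx``, which is robust for
    arguments from the underflow range up to far beyond overflow of
    ``exp``.  Used by the likelihood hot path, where the W argument is
    always positive.
    """
    # below ~e^-45 the quadratic correction is under double precision:
    # W0(z) = z - z^2 + ... == z exactly
    tiny = lx < -45.0
    lx_safe = np.where(tiny, 0.0, lx)
    big = lx_safe > 1.0
    w = np.where(big,
                 lx_safe - np.log(np.where(big, lx_safe, 2.0)),
                 np.log1p(np.exp(np.minimum(lx_safe, 1.0))))
    for _ in range(6):
        w = w - (w + np.log(w) - lx_safe) * w / (w + 1.0)
    return np.where(tiny, np.exp(np.clip(lx, -745.0, 0.0)), w)


def predict_consumed(params: FRParams, geom: TrialGeometry) -> float:
    """Expected prey consumed under prey depletion (Rogers' equation).

    Returns the unique root ``N_e`` in ``[0, N_0]`` of
    ``N_e = N_0(1 - exp(a(N_e h - T)))`` via the Lambert-W closed form.
    Degenerate parameter values fall to analytic limits: no attacks
    (``a = 0``) give 0; no handling (``h = 0``) gives exponential
    depletion ``N_0(1 - exp(-aT))``.
    """
    return float(
        _predict_consumed_arrays(
            params.attack_rate, params.handling_time,
            float(geom.initial_density), geom.duration,
        )
    )


def _predict_consumed_arrays(a, h, n0, T):
    """Vectorised Rogers prediction on raw floats (no validation).

    ``a`` and ``h`` are scalars; ``n0``/``T`` may be arrays. Used by the
    fitting hot loop and the simulator.
    """
    n0_in = np.asarray(n0, dtype=float)
    scalar = n0_in.ndim == 0 and np.ndim(T) == 0
    n0v, Tv = np.atleast_1d(*np.broadcast_arrays(n0_in, np.asarray(T, dtype=float)))

    if a == 0.0:
        ne = np.zeros_like(n0v)
    elif h == 0.0:
        ne = n0v * -np.expm1(-a * Tv)
    else:
        ne = np.zeros_like(n0v)
        pos = n0v > 0
        if np.any(pos):
            n0p, Tp = n0v[pos], Tv[pos]
            # argument computed in log space: a*h*N0 * exp(-a(T - h N0)) can overflow
            log_arg = np.log(a * h * n0p) - a * (Tp - h * n0p)
            w = _w0_exp(log_arg)
            ne[pos] = n0p - w / (a * h)
    np.clip(ne, 0.0, n0v, out=ne)
    return float(ne[0]) if scalar else ne


def max_feeding_rate(h: float) -> float:
    """Maximum feeding rate ``1/h``, in prey per trial duration.

    With time trial-normalised this is "prey per 4 h" for the 4-h arena
    design.  Raises for non-positive handling time.
    """
    if not h > 0:
        raise ValueError(f"handling time must be positive to derive a maximum feeding rate, got {h}")
    return 1.0 / h
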