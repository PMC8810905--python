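"""Synthetic feeding-trial generation.

Emulates closed-arena prey-depletion trials: a single predator (juvenile
trout fry) foraging on chironomid larvae for one 4-h trial, across six
prey densities with predator-free control arenas.  The default design
mirrors the published experiment: 3 fish types (diploid rainbow, diploid
brown, triploid brown) x 2 prey-novelty levels x 6 densities
(1, 2, 4, 8, 16, 32) x 3 replicates, plus 3 control arenas per density,
with Type II consumption at the published attack-rate / handling-time
magnitudes.

Two noise mechanisms are available:

``binomial``
    Eaten ~ Binomial(N_0, N_e/N_0) around the Rogers expectation — the
    same distribution the fitting likelihood assumes, so parameter
    recovery is a clean test of the estimator.
``event_driven``
    A continuous-time search/handle renewal process: encounters arrive
    at rate a x (remaining prey), each capture blocks the predator for a
    handling interval h.  Generates depletion noise without assuming the
    fitted likelihood, for robustness checks.

Controls have zero background mortality by default (the experimental
observation); a ``background_mortality`` rate exists for robustness
tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .core import FRParams, _predict_consumed_arrays

__all__ = [
    "FISH_TYPES",
    "NOVELTY_LEVELS",
    "TROUT_GROUP_PARAMS",
    "FeedingTrial",
    "SimDesign",
    "simulate_trials",
    "trout_design",
    "trials_to_frame",
]

FISH_TYPES = ("rainbow_diploid", "brown_diploid", "brown_triploid")
NOVELTY_LEVELS = ("novel", "not_novel")

#: Published point estimates (attack rate, handling time) per
#: (fish_type, novelty) group, in trial-normalised time (T = 1 is 4 h).
TROUT_GROUP_PARAMS: dict[tuple[str, str], FRParams] = {
    ("rainbow_diploid", "novel"): FRParams(13.995, 0.100),
    ("brown_diploid", "novel"): FRParams(4.720, 0.063),
    ("brown_triploid", "novel"): FRParams(33.970, 0.092),
    ("rainbow_diploid", "not_novel"): FRParams(4.223, 0.085),
    ("brown_diploid", "not_novel"): FRParams(5.873, 0.045),
    ("brown_triploid", "not_novel"): FRParams(40.915, 0.100),
}

#: Label used in the fish_type / novelty columns of predator-free rows.
CONTROL_LABEL = "control"


@dataclass(frozen=True)
class FeedingTrial:
    """One arena trial: a predator (or a predator-free control) with prey."""

    fish_type: str
    novelty: str
    initial_density: int
    eaten: int
    duration: float = 1.0
    is_control: bool = False
    replicate_id: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.eaten <= self.initial_density:
            raise ValueError(
                f"eaten must be in [0, initial_density], got {self.eaten} of {self.initial_density}"
            )


@dataclass(frozen=True)
class SimDesign:
    """Design of a simulated feeding experiment.

    ``true_params`` maps (fish_type, novelty) cells to the generating
    FRParams; ``mechanism`` chooses the noise model; ``seed`` is
    mandatory so every dataset is reproducible.
    """

    seed: int
    densities: tuple[int, ...] = (1, 2, 4, 8, 16, 32)
    reps_per_density: int = 3
    duration: float = 1.0
    true_params: dict[tuple[str, str], FRParams] = field(
        default_factory=lambda: dict(TROUT_GROUP_PARAMS)
    )
    mechanism: str = "binomial"
    control_reps: int = 3
    background_mortality: float = 0.0

    def __post_init__(self) -> None:
        if self.reps_per_density <= 0 or self.control_reps < 0:
            raise ValueError("replicate counts must be positive")
        if self.duration <= 0:
            raise ValueError("duration must be positive")
        if self.mechanism not in ("binomial", "event_driven"):
            raise ValueError(f"unknown mechanism {self.mechanism!r}")
        if not 0.0 <= self.background_mortality < 1.0:
            raise ValueError("background_mortality must be in [0, 1)")
        for key, p in self.true_params.items():
            if p.attack_rate < 0 or p.handling_time < 0:
                raise ValueError(f"negative rate in true_params for {key}")


def trout_design(seed: int, **overrides) -> SimDesign:
    """The full published trout-chironomid design as a simulation preset.

    3 fish types x 2 novelty levels x 6 densities x 3 replicates = 108
    predator trials, plus 3 predator-free controls per density (18 rows),
    4-h trials (duration 1.0), published (a, h) per group as truth.
    """
    return replace(SimDesign(seed=seed), **overrides) if overrides else SimDesign(seed=seed)


def _draw_binomial(rng: np.random.Generator, p: FRParams, n0: int, T: float) -> int:
    ne = _predict_consumed_arrays(p.attack_rate, p.handling_time, float(n0), T)
    prob = min(max(ne / n0, 0.0), 1.0) if n0 > 0 else 0.0
    return int(rng.binomial(n0, prob))


def _draw_event_driven(rng: np.random.Generator, p: FRParams, n0: int, T: float) -> int:
    """Search/handle renewal process run to the end of the trial.

    While searching, the next encounter is exponential with rate
    a x (remaining prey); a capture at time t <= T counts as eaten and
    blocks searching for a handling interval h.
    """
    a, h = p.attack_rate, p.handling_time
    if a == 0.0 or n0 == 0:
        return 0
    t, remaining, eaten = 0.0, n0, 0
    while remaining > 0:
        rate = a * remaining
        t += rng.exponential(1.0 / rate)
        if t > T:
            break
        eaten += 1
        remaining -= 1
        t += h
        if t >= T:
            break
    return eaten


def simulate_trials(design: SimDesign) -> pd.DataFrame:
    """Generate a full trial table under the given design.

    Returns a DataFrame in the shared trials schema (fish_type, novelty,
    initial_density, eaten, duration, is_control, replicate_id), with
    predator rows for every (group, density, replicate) cell followed by
    control rows.  Identical designs (including seed) yield identical
    tables.
    """
    rng = np.random.default_rng(design.seed)
    rows: list[dict] = []

    for fish_type, novelty in sorted(design.true_params):
        p = design.true_params[(fish_type, novelty)]
        for n0 in design.densities:
            for rep in range(design.reps_per_density):
                if design.mechanism == "binomial":
                    eaten = _draw_binomial(rng, p, int(n0), design.duration)
                else:
                    eaten = _draw_event_driven(rng, p, int(n0), design.duration)
                rows.append({
                    "fish_type": fish_type, "novelty": novelty,
                    "initial_density": int(n0), "eaten": eaten,
                    "duration": design.duration, "is_control": False,
                    "replicate_id": rep,
                })

    for n0 in design.densities:
        for rep in range(design.control_reps):
            dead = int(rng.binomial(int(n0), design.background_mortality)) \
                if design.background_mortality > 0 else 0
            rows.append({
                "fish_type": CONTROL_LABEL, "novelty": CONTROL_LABEL,
                "initial_density": int(n0), "eaten": dead,
                "duration": design.duration, "is_control": True,
                "replicate_id": rep,
            })

    return pd.DataFrame(rows)


def trials_to_frame(trials: list[FeedingTrial]) -> pd.DataFrame:
    """Convert typed FeedingTrial records to the shared schema frame."""
    return pd.DataFrame([{
        "fish_type": t.fish_type, "novelty": t.novelty,
        "initial_density": t.initial_density, "eaten": t.eaten,
        "duration": t.duration, "is_control": t.is_control,
        "replicate_id": t.replicate_id,
    } for t in trials])
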