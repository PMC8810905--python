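import numpy as np
import pandas as pd
import pytest

import frfit
from frfit.simulate import SimDesign, TROUT_GROUP_PARAMS


@pytest.fixture(scope="session")
def preset_trials() -> pd.DataFrame:
    """One full simulated experiment (108 predator + 18 control rows)."""
    return frfit.simulate_trials(frfit.trout_design(seed=42))


@pytest.fixture(scope="session")
def brown_novel_trials(preset_trials) -> pd.DataFrame:
    """The (brown_diploid, novel) group of the fixed-seed experiment."""
    t = preset_trials
    return t[(t.fish_type == "brown_diploid") & (t.novelty == "novel")]


@pytest.fixture(scope="session")
def single_group_design():
    """Factory for a one-group design at the published brown-diploid/novel
    magnitudes (a = 4.72, h = 0.063)."""
    params = TROUT_GROUP_PARAMS[("brown_diploid", "novel")]

    def make(seed: int, **overrides) -> SimDesign:
        kw = dict(seed=seed, true_params={("brown_diploid", "novel"): params},
                  control_reps=0)
        kw.update(overrides)
        return SimDesign(**kw)

    return make


def rogers_fixed_point(a: float, h: float, n0: float, T: float = 1.0) -> float:
    """Independent bisection solver for N_e = N_0(1 - exp(a(N_e h - T))).

    Oracle for the Lambert-W closed form; deliberately avoids frfit code.
    """
    import math

    if a == 0.0 or n0 == 0:
        return 0.0
    lo, hi = 0.0, float(n0)
    for _ in range(200):
        mid = (lo + hi) / 2.0
        expo = a * (mid * h - T)
        g = -math.inf if expo > 700 else n0 * (1.0 - math.exp(expo)) - mid
        if g > 0:
            lo = mid
        else:
            hi = mid
    return (lo + hi) / 2.0
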