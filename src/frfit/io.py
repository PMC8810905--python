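"""Reading, writing and validating the shared trials table.

The on-disk format is a UTF-8 CSV with a header row and '.' decimals,
one row per arena trial, columns: fish_type, novelty, initial_density,
eaten, duration, is_control, replicate_id.  Simulated and field data use
the same schema so downstream stages cannot tell them apart.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .exceptions import SchemaError, ValidationError

__all__ = ["REQUIRED_COLUMNS", "read_trials", "write_trials", "check_controls", "ControlSummary"]

REQUIRED_COLUMNS = (
    "fish_type", "novelty", "initial_density", "eaten",
    "duration", "is_control", "replicate_id",
)

_DTYPES = {
    "fish_type": str, "novelty": str, "initial_density": int, "eaten": int,
    "duration": float, "is_control": bool, "replicate_id": int,
}


def read_trials(path) -> pd.DataFrame:
    """Read and validate a trials CSV.

    Raises
    ------
    SchemaError
        Missing/empty file content or missing required columns.
    ValidationError
        Row-level violations (negative counts, eaten > offered,
        non-positive duration), reported with 1-based file line numbers
        (header is line 1).
    """
    try:
        df = pd.read_csv(path)
    except pd.errors.EmptyDataError as exc:
        raise SchemaError(f"{path}: file is empty or has no header") from exc

    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing required columns: {', '.join(missing)}")

    violations = []
    for pos, (_, row) in enumerate(df.iterrows()):
        line = pos + 2  # header is line 1
        try:
            n0 = int(row["initial_density"])
            eaten = int(row["eaten"])
            dur = float(row["duration"])
        except (TypeError, ValueError):
            violations.append((line, "non-numeric initial_density/eaten/duration"))
            continue
        if n0 < 0:
            violations.append((line, f"negative initial_density {n0}"))
        if eaten < 0:
            violations.append((line, f"negative eaten count {eaten}"))
        elif eaten > n0:
            violations.append((line, f"eaten {eaten} exceeds initial_density {n0}"))
        if not dur > 0:
            violations.append((line, f"non-positive duration {dur}"))
    if violations:
        raise ValidationError(violations)

    return df.astype(_DTYPES)[list(REQUIRED_COLUMNS)]


def write_trials(trials: pd.DataFrame, path) -> None:
    """Write a trials table in the shared CSV schema."""
    trials[list(REQUIRED_COLUMNS)].to_csv(path, index=False)


@dataclass(frozen=True)
class ControlSummary:
    """Outcome of the predator-free control check.

    100% control survival licenses attributing all experimental deaths
    to predation; anything less annotates the analysis with per-density
    background mortality.
    """

    n_controls: int
    survival_pct: float | None
    deaths_attributable_to_predation: bool
    message: str
    background_mortality_by_density: dict[int, float] = field(default_factory=dict)


def check_controls(trials: pd.DataFrame) -> ControlSummary:
    """Summarise predator-free control survival.

    Absence of control rows yields a notice (not an error); survival
    below 100% produces a warning message and per-density mortality
    rates, and downstream analysis may proceed with the annotation.
    """
    if "is_control" not in trials.columns:
        controls = trials.iloc[0:0]
    else:
        controls = trials.loc[trials["is_control"].astype(bool)]
    if len(controls) == 0:
        return ControlSummary(
            n_controls=0, survival_pct=None,
            deaths_attributable_to_predation=False,
            message="no controls: prey mortality from causes other than predation is unquantified",
        )

    offered = controls["initial_density"].sum()
    dead = controls["eaten"].sum()
    survival = 100.0 * (1.0 - dead / offered) if offered > 0 else 100.0
    if dead == 0:
        return ControlSummary(
            n_controls=len(controls), survival_pct=float(survival),
            deaths_attributable_to_predation=True,
            message="prey survival in predator-free controls was 100%; "
                    "experimental deaths attributed to predation",
        )

    by_density = {
        int(d): float(g["eaten"].sum() / g["initial_density"].sum())
        for d, g in controls.groupby("initial_density")
    }
    return ControlSummary(
        n_controls=len(controls), survival_pct=float(survival),
        deaths_attributable_to_predation=False,
        message=f"warning: control survival {survival:.1f}% < 100%; background "
                "mortality present, predation estimates may be inflated",
        background_mortality_by_density=by_density,
    )
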