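"""End-to-end orchestration of the functional-response analysis.

For each (fish_type, novelty) group in a trials table: classify the
response type from the logistic density test, fit Rogers' random
predator equation by maximum likelihood, and bootstrap confidence
intervals and curve bands.  Emits a report in the published table layout
(first-order term, type label, a with p, h with p, 1/h, 95% CIs) as TSV
plus a machine-readable JSON twin, and a tidy per-density band table for
plotting confidence clouds around the fitted curves.
"""

from __future__ import annotations

import json
import logging
import zlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import __version__
from .fitting import BootstrapSummary, bootstrap_fr, fit_rogers
from .io import ControlSummary, check_controls, read_trials
from .typetest import classify_fr_type

__all__ = ["PipelineConfig", "AnalysisReport", "run_pipeline"]

logger = logging.getLogger("frfit")


@dataclass(frozen=True)
class PipelineConfig:
    """Knobs of the end-to-end analysis run."""

    seed: int = 0
    alpha: float = 0.05
    n_boot: int = 2000
    stratified_boot: bool = False
    bca: bool = False
    density_grid: tuple[float, ...] | None = None


@dataclass
class AnalysisReport:
    """Per-group results plus the controls block and run metadata."""

    rows: list[dict]
    controls: ControlSummary
    metadata: dict
    bands: pd.DataFrame
    draws: pd.DataFrame | None = None

    # column order mirrors the published summary table
    TABLE_COLUMNS = (
        "fish_type", "novelty", "first_order_term", "fr_type",
        "attack_rate", "p_attack", "handling_time", "p_handling",
        "max_feeding_rate", "ci_a_lower", "ci_a_upper",
        "ci_h_lower", "ci_h_upper", "n_trials",
    )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.rows, columns=list(self.TABLE_COLUMNS))

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False, float_format="%.6g")

    def to_json(self, path=None) -> str:
        payload = {
            "groups": self.rows,
            "controls": {
                "n_controls": self.controls.n_controls,
                "survival_pct": self.controls.survival_pct,
                "deaths_attributable_to_predation":
                    self.controls.deaths_attributable_to_predation,
                "message": self.controls.message,
                "background_mortality_by_density":
                    {str(k): v for k, v in
                     self.controls.background_mortality_by_density.items()},
            },
            "metadata": self.metadata,
        }
        text = json.dumps(payload, indent=2, sort_keys=True, allow_nan=True)
        if path is not None:
            with open(path, "w", encoding="utf-8") as fh:
                fh.write(text)
        return text

    def write_bands(self, path) -> None:
        self.bands.to_csv(path, index=False, float_format="%.8g")


def significance_stars(p: float) -> str:
    """Conventional significance stars: *** <0.001, ** <0.01, * <0.05."""
    if not np.isfinite(p):
        return ""
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return ""


def _group_seed(seed: int, fish_type: str, novelty: str) -> int:
    """Deterministic per-group bootstrap seed, independent of the other
    groups present (so deleting one group cannot shift another's draws)."""
    crc = zlib.crc32(f"{fish_type}|{novelty}".encode())
    return int((seed * 1_000_003 + crc) % 2**31)


def run_pipeline(trials, config: PipelineConfig = PipelineConfig()) -> AnalysisReport:
    """Run classification, fitting and bootstrap for every predator group.

    Parameters
    ----------
    trials : DataFrame or path
        Trials in the shared schema, or a CSV path readable by
        :func:`frfit.io.read_trials`.
    config : PipelineConfig

    Returns
    -------
    AnalysisReport
        One row per (fish_type, novelty) group, the controls block, the
        bootstrap band table, and run metadata.  Deterministic for a
        fixed seed and config.

    Module errors (insufficient data, non-convergence, bootstrap
    instability) propagate annotated with the offending group.
    """
    if not isinstance(trials, pd.DataFrame):
        trials = read_trials(trials)

    controls = check_controls(trials)
    logger.info("controls: %s", controls.message)

    predators = trials.loc[~trials["is_control"].astype(bool)]
    grid = None if config.density_grid is None else np.asarray(config.density_grid, float)

    rows: list[dict] = []
    band_frames: list[pd.DataFrame] = []
    draw_frames: list[pd.DataFrame] = []
    for (fish_type, novelty), sub in sorted(
        predators.groupby(["fish_type", "novelty"], sort=False),
        key=lambda kv: kv[0],
    ):
        try:
            tt = classify_fr_type(sub, alpha=config.alpha)
            fit = fit_rogers(sub, group=(fish_type, novelty))
            boot = bootstrap_fr(
                sub, n_boot=config.n_boot,
                seed=_group_seed(config.seed, fish_type, novelty),
                density_grid=grid, stratified=config.stratified_boot,
                bca=config.bca, fit=fit,
            )
        except Exception as exc:
            raise type(exc)(f"group ({fish_type}, {novelty}): {exc}") from exc
        if boot.n_failed or boot.n_redrawn:
            logger.info(
                "group (%s, %s): %d replicates failed, %d degenerate resamples redrawn",
                fish_type, novelty, boot.n_failed, boot.n_redrawn,
            )

        rows.append({
            "fish_type": fish_type,
            "novelty": novelty,
            "first_order_term": round(tt.first_order, 6),
            "first_order_stars": significance_stars(tt.p_first),
            "fr_type": tt.label,
            "attack_rate": round(fit.params.attack_rate, 6),
            "p_attack": round(fit.p_a, 6) if np.isfinite(fit.p_a) else None,
            "attack_stars": significance_stars(fit.p_a),
            "handling_time": round(fit.params.handling_time, 6),
            "p_handling": round(fit.p_h, 6) if np.isfinite(fit.p_h) else None,
            "handling_stars": significance_stars(fit.p_h),
            "max_feeding_rate": round(fit.max_feeding_rate, 6),
            "ci_a_lower": round(boot.ci_a[0], 6), "ci_a_upper": round(boot.ci_a[1], 6),
            "ci_h_lower": round(boot.ci_h[0], 6), "ci_h_upper": round(boot.ci_h[1], 6),
            "n_trials": fit.n_trials,
        })
        bf = boot.band.copy()
        bf.insert(0, "fish_type", fish_type)
        bf.insert(1, "novelty", novelty)
        band_frames.append(bf)
        df = pd.DataFrame(boot.draws, columns=["attack_rate", "handling_time"])
        df.insert(0, "fish_type", fish_type)
        df.insert(1, "novelty", novelty)
        draw_frames.append(df)

    bands = pd.concat(band_frames, ignore_index=True) if band_frames else pd.DataFrame(
        columns=["fish_type", "novelty", "density", "lower", "point", "upper"]
    )
    draws = pd.concat(draw_frames, ignore_index=True) if draw_frames else None

    metadata = {
        "seed": config.seed, "alpha": config.alpha, "n_boot": config.n_boot,
        "stratified_boot": config.stratified_boot, "bca": config.bca,
        "software": f"frfit {__version__}",
    }
    return AnalysisReport(rows=rows, controls=controls, metadata=metadata,
                          bands=bands, draws=draws)
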