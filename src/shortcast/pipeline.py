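"""End-to-end pipeline: synthetic world -> cleaning -> score -> features ->
per-IG models -> evaluation.

The analysis scripts and the acceptance checks drive these stages; each
stage is a thin composition of the module-level operations so results are
identical whether run here or step by step.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .config import SimConfig
from .evaluation import EvalReport, evaluate_forecasts
from .features import FeatureTable, assemble_features
from .impact import impact_series
from .ingest import CleaningLog, build_intervals
from .model import Hyperparams, forecast_holdout, make_blocked_splits
from .synthetic import SimWorld, simulate_world

__all__ = ["PipelineResult", "run_pipeline", "score_world"]


@dataclass
class PipelineResult:
    world: SimWorld
    intervals: pd.DataFrame
    cleaning_log: CleaningLog
    impact: pd.DataFrame
    features: FeatureTable
    forecasts: pd.DataFrame
    report: EvalReport


def score_world(world: SimWorld, earliest: str = "2017-03-01") -> tuple[pd.DataFrame, CleaningLog, pd.DataFrame]:
    """Clean the world's raw reports and compute the monthly impact series."""
    months = world.config.month_index
    last_day = pd.Timestamp(months[-1].end_time.date())
    intervals, log = build_intervals(world.reports, world.packs, earliest=earliest, clamp_end=last_day)
    imp = impact_series(world.dispense, intervals, world.packs, world.catalog, months)
    return intervals, log, imp


def run_pipeline(
    config: SimConfig,
    holdout_months: int = 4,
    seed: int = 0,
    hyperparams: Hyperparams | None = None,
    earliest: str = "2017-03-01",
) -> PipelineResult:
    """Simulate, clean, score, featurise, forecast the holdout, evaluate.

    ``holdout_months`` final months are held out; each IG's model is refit
    on everything before them and produces one-step-ahead forecasts.
    """
    world = simulate_world(config)
    intervals, log, imp = score_world(world, earliest=earliest)
    feats = assemble_features(world.dispense, imp, world.catalog)
    months = config.month_index
    holdout = [str(m) for m in months[-holdout_months:]]
    forecasts, _models = forecast_holdout(feats, holdout, hyperparams=hyperparams, seed=seed)
    report = evaluate_forecasts(forecasts)
    return PipelineResult(world, intervals, log, imp, feats, forecasts, report)
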