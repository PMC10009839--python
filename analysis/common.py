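"""Shared study configuration and paths for the numbered analysis scripts.

The study conditions: 100 interchangeable groups observed January 2017 to
April 2021; January 2017 - December 2020 is the train/test span (36 blocked
resamples) and January - April 2021 the 4-month holdout.
"""

from pathlib import Path

from shortcast import SimConfig

REPO = Path(__file__).resolve().parents[1]
RESULTS = REPO / "results"          # small summary tables (kept)
SCRATCH = REPO / "scratch" / "analysis"  # bulky intermediates (not kept)

SEED = 2021

STUDY_CONFIG = SimConfig(seed=SEED)  # defaults are the study conditions

HOLDOUT_MONTHS = [str(m) for m in STUDY_CONFIG.month_index[-4:]]
TRAIN_MONTHS = [str(m) for m in STUDY_CONFIG.month_index[:-4]]


def ensure_dirs() -> None:
    RESULTS.mkdir(parents=True, exist_ok=True)
    SCRATCH.mkdir(parents=True, exist_ok=True)
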