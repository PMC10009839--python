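"""Compute the monthly shortage impact score for every IG.

The outcome variable: per IG and month, the historical-DOS-weighted
fraction of component DIN pack listings unavailable, in [0, 1].
"""

import json

import pandas as pd

from common import RESULTS, SCRATCH, STUDY_CONFIG, ensure_dirs
from shortcast.impact import impact_series
from shortcast.ingest import read_intervals


def main() -> None:
    ensure_dirs()
    data = SCRATCH / "data"
    dispense = pd.read_csv(data / "dispense.csv")
    packs = pd.read_csv(data / "packs.csv")
    catalog = pd.read_csv(data / "catalog.csv")
    intervals = read_intervals(SCRATCH / "shortage_intervals.csv")

    imp = impact_series(dispense, intervals, packs, catalog, STUDY_CONFIG.month_index)
    imp.to_csv(SCRATCH / "impact_scores.csv", index=False)

    nonzero = imp[imp["score"] > 0]
    summary = {
        "n_ig_months": len(imp),
        "n_nonzero": len(nonzero),
        "share_nonzero": round(len(nonzero) / len(imp), 4),
        "mean_nonzero_score": round(float(nonzero["score"].mean()), 4),
        "n_impactful_ig_months": int((imp["score"] >= 0.5).sum()),
        "max_score": round(float(imp["score"].max()), 4),
    }
    (RESULTS / "impact_summary.json").write_text(json.dumps(summary, indent=2) + "\n")
    print("Impact series:", json.dumps(summary, indent=2))


if __name__ == "__main__":
    main()
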