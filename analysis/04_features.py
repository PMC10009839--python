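"""Assemble the lagged per-IG feature table.

Per-DIN and IG-level demand aggregates, share-change and Gini preference
measures, therapeutic-class neighbour shortage pressure, all at lags 1-4.
Frames are pickled per IG to scratch; the column manifest goes to results.
"""

import json
import pickle

import pandas as pd

from common import RESULTS, SCRATCH, ensure_dirs
from shortcast.features import assemble_features


def main() -> None:
    ensure_dirs()
    data = SCRATCH / "data"
    dispense = pd.read_csv(data / "dispense.csv")
    catalog = pd.read_csv(data / "catalog.csv")
    impact = pd.read_csv(SCRATCH / "impact_scores.csv")

    feats = assemble_features(dispense, impact, catalog, lags=4)
    with open(SCRATCH / "features.pkl", "wb") as fh:
        pickle.dump(feats, fh)
    feats.schema.to_csv(SCRATCH / "features_schema.csv", index=False)

    n_cols = {ig: t.shape[1] - 1 for ig, t in feats.frames.items()}
    summary = {
        "n_igs": len(feats.frames),
        "n_rows_per_ig": int(next(iter(feats.frames.values())).shape[0]),
        "predictor_columns_min": min(n_cols.values()),
        "predictor_columns_max": max(n_cols.values()),
        "families": sorted(feats.schema["family"].unique()),
    }
    (RESULTS / "features_summary.json").write_text(json.dumps(summary, indent=2) + "\n")
    print("Feature table:", json.dumps(summary, indent=2))


if __name__ == "__main__":
    main()
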