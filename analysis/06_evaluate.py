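"""Evaluate the holdout forecasts.

MAE and its per-bin breakdown, the 4-class confusion matrix with accuracy
(exact 95% CI) and Cohen's kappa, per-class precision/recall/specificity,
the impactful-shortage detection table, and an MAE histogram.
"""

import pandas as pd

from common import RESULTS, SCRATCH, ensure_dirs
from shortcast.evaluation import evaluate_forecasts


def main() -> None:
    ensure_dirs()
    forecasts = pd.read_csv(RESULTS / "forecasts.csv")
    report = evaluate_forecasts(forecasts, threshold=0.5)

    report.to_json(RESULTS / "eval_report.json")
    report.confusion.to_csv(RESULTS / "confusion_matrix.csv")
    report.impactful_table.round(3).to_csv(RESULTS / "impactful_table.csv", index=False)
    report.mae_by_bin.round(3).to_csv(RESULTS / "mae_by_bin.csv")
    report.class_metrics.round(3).to_csv(RESULTS / "class_metrics.csv")

    try:
        import matplotlib

        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        fig, ax = plt.subplots(figsize=(6, 4))
        err = (forecasts["actual"] - forecasts["forecast"]).abs()
        ax.hist(err, bins=40)
        ax.set_xlabel("absolute forecast error")
        ax.set_ylabel("holdout forecasts")
        fig.tight_layout()
        fig.savefig(SCRATCH / "mae_histogram.png", dpi=120)
    except ImportError:
        pass

    n_det = int(report.impactful_table["detected"].sum()) if len(report.impactful_table) else 0
    print(f"holdout MAE {report.mae_overall:.4f}")
    print(f"accuracy {report.accuracy:.3f} (95% CI {report.accuracy_ci95[0]:.3f}-"
          f"{report.accuracy_ci95[1]:.3f}), kappa {report.kappa:.3f}")
    print(f"impactful shortages detected: {n_det}/{len(report.impactful_table)}")
    print("\nConfusion matrix (actual x forecast):")
    print(report.confusion)
    print("\nErrors by actual bin:")
    print(report.mae_by_bin.round(3))


if __name__ == "__main__":
    main()
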