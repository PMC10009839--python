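"""Evaluation battery for shortage-impact forecasts.

Forecast quality is summarised three ways:

* **MAE** — mean absolute error of the score forecasts, overall, per IG,
  and broken down by the actual score's severity bin;
* **ordinal 4-class agreement** — scores are binned None / Low / Medium /
  High (0; (0, 0.33]; (0.33, 0.67]; (0.67, 1]), and the actual-vs-forecast
  confusion matrix yields accuracy with an exact (Clopper-Pearson) 95% CI,
  unweighted Cohen's kappa, and one-vs-rest precision / recall /
  specificity per class;
* **impactful-shortage detection** — an IG-month with actual score >= 0.5
  (at least half the group unavailable) is an impactful shortage; it counts
  as detected when the forecast is also >= 0.5.

Undefined ratios (empty classes, no impactful shortages) surface as NaN,
never as a silent zero.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.stats import binomtest

__all__ = [
    "BINS",
    "bin_score",
    "mae",
    "mae_by_bin",
    "confusion_and_agreement",
    "class_metrics",
    "impactful_detection",
    "EvalReport",
    "evaluate_forecasts",
]

BINS = ("None", "Low", "Medium", "High")
_EDGES = (0.0, 0.33, 0.67, 1.0)


def bin_score(score):
    """Severity bin of an impact score: 0 -> None, then (0,.33], (.33,.67], (.67,1]."""
    arr = np.asarray(score, dtype=float)
    if np.any((arr < 0) | (arr > 1)):
        raise ValueError("impact scores must lie in [0, 1]")
    idx = np.digitize(arr, _EDGES[1:], right=True) + 1  # Low..High
    idx = np.where(arr == 0.0, 0, idx)
    # a 0-d index into an object array yields the bare str already
    return np.asarray(BINS, dtype=object)[idx]


def mae(records: pd.DataFrame) -> float:
    """Mean absolute error of the forecasts."""
    if records.empty:
        raise ValueError("cannot compute MAE of zero forecast records")
    return float((records["actual"] - records["forecast"]).abs().mean())


def mae_per_ig(records: pd.DataFrame) -> pd.Series:
    err = (records["actual"] - records["forecast"]).abs()
    return err.groupby(records["ig_code"]).mean().rename("mae")


def mae_by_bin(records: pd.DataFrame) -> pd.DataFrame:
    """Mean actual, mean forecast and MAE grouped by the ACTUAL score's bin."""
    df = records.copy()
    df["bin"] = bin_score(df["actual"].to_numpy())
    df["abs_err"] = (df["actual"] - df["forecast"]).abs()
    out = (
        df.groupby("bin")
        .agg(mean_actual=("actual", "mean"), mean_forecast=("forecast", "mean"), mae=("abs_err", "mean"))
        .reindex(BINS)
    )
    out.index.name = "bin"
    return out


def confusion_matrix(records: pd.DataFrame) -> pd.DataFrame:
    """4x4 actual-bin x forecast-bin contingency table (all bins present)."""
    actual = pd.Categorical(bin_score(records["actual"].to_numpy()), categories=BINS)
    forecast = pd.Categorical(bin_score(records["forecast"].to_numpy()), categories=BINS)
    return pd.crosstab(
        pd.Series(actual, name="actual"), pd.Series(forecast, name="forecast"), dropna=False
    ).reindex(index=BINS, columns=BINS, fill_value=0)


def _kappa_from_matrix(m: np.ndarray) -> float:
    n = m.sum()
    p_o = np.trace(m) / n
    p_e = float((m.sum(axis=1) * m.sum(axis=0)).sum()) / (n * n)
    if p_e == 1.0:
        return 1.0 if p_o == 1.0 else 0.0
    return float((p_o - p_e) / (1.0 - p_e))


def confusion_and_agreement(
    records: pd.DataFrame, ci_method: str = "exact"
) -> tuple[pd.DataFrame, float, tuple[float, float], float]:
    """Confusion matrix, accuracy, 95% CI on accuracy, and Cohen's kappa.

    The CI is the exact binomial (Clopper-Pearson) interval by default;
    ``ci_method="wilson"`` selects the normal-score alternative.
    """
    if records.empty:
        raise ValueError("no forecast records")
    matrix = confusion_matrix(records)
    m = matrix.to_numpy()
    n = int(m.sum())
    correct = int(np.trace(m))
    accuracy = correct / n
    ci = binomtest(correct, n).proportion_ci(confidence_level=0.95, method=ci_method)
    kappa = _kappa_from_matrix(m.astype(float))
    return matrix, float(accuracy), (float(ci.low), float(ci.high)), kappa


def class_metrics(matrix: pd.DataFrame) -> pd.DataFrame:
    """One-vs-rest precision, recall and specificity per class.

    Ratios with a zero denominator are NaN with ``*_defined`` False — a
    class absent from the forecasts has no precision, not a precision of 0.
    """
    m = matrix.to_numpy(dtype=float)
    if m.shape[0] != m.shape[1]:
        raise ValueError("confusion matrix must be square")
    total = m.sum()
    rows = []
    for i, name in enumerate(matrix.index):
        tp = m[i, i]
        fn = m[i, :].sum() - tp
        fp = m[:, i].sum() - tp
        tn = total - tp - fn - fp
        rows.append(
            {
                "class": name,
                "precision": tp / (tp + fp) if tp + fp > 0 else np.nan,
                "precision_defined": tp + fp > 0,
                "recall": tp / (tp + fn) if tp + fn > 0 else np.nan,
                "recall_defined": tp + fn > 0,
                "specificity": tn / (tn + fp) if tn + fp > 0 else np.nan,
                "specificity_defined": tn + fp > 0,
            }
        )
    return pd.DataFrame(rows).set_index("class")


def impactful_detection(
    records: pd.DataFrame, threshold: float = 0.5
) -> tuple[pd.DataFrame, float]:
    """Detection table and rate for impactful shortages (actual >= threshold).

    A shortage is detected when the forecast also reaches the threshold.
    The rate is NaN when no impactful shortage occurred.
    """
    table = records[records["actual"] >= threshold].copy()
    table["detected"] = table["forecast"] >= threshold
    rate = float(table["detected"].mean()) if len(table) else float("nan")
    return table, rate


@dataclass
class EvalReport:
    """Everything the evaluation battery computes, JSON-serialisable."""

    n_records: int
    mae_overall: float
    mae_per_ig: pd.Series
    mae_by_bin: pd.DataFrame
    confusion: pd.DataFrame
    accuracy: float
    accuracy_ci95: tuple[float, float]
    kappa: float
    class_metrics: pd.DataFrame
    impactful_table: pd.DataFrame
    detection_rate: float

    def to_dict(self) -> dict:
        return {
            "n_records": self.n_records,
            "mae_overall": self.mae_overall,
            "mae_by_bin": self.mae_by_bin.reset_index().to_dict(orient="records"),
            "confusion": self.confusion.to_numpy().tolist(),
            "accuracy": self.accuracy,
            "accuracy_ci95": list(self.accuracy_ci95),
            "kappa": self.kappa,
            "class_metrics": self.class_metrics.reset_index().to_dict(orient="records"),
            "n_impactful": int(len(self.impactful_table)),
            "n_detected": int(self.impactful_table["detected"].sum()) if len(self.impactful_table) else 0,
            "detection_rate": None if np.isnan(self.detection_rate) else self.detection_rate,
        }

    def to_json(self, path: str | Path) -> None:
        def _default(o):
            if isinstance(o, (np.floating, np.integer)):
                return o.item()
            if isinstance(o, np.bool_):
                return bool(o)
            raise TypeError(type(o))

        Path(path).write_text(json.dumps(self.to_dict(), indent=2, default=_default) + "\n")


def evaluate_forecasts(records: pd.DataFrame, threshold: float = 0.5) -> EvalReport:
    """Run the full battery on holdout forecast records."""
    matrix, accuracy, ci, kappa = confusion_and_agreement(records)
    table, rate = impactful_detection(records, threshold)
    return EvalReport(
        n_records=len(records),
        mae_overall=mae(records),
        mae_per_ig=mae_per_ig(records) if "ig_code" in records else pd.Series(dtype=float),
        mae_by_bin=mae_by_bin(records),
        confusion=matrix,
        accuracy=accuracy,
        accuracy_ci95=ci,
        kappa=kappa,
        class_metrics=class_metrics(matrix),
        impactful_table=table,
        detection_rate=rate,
    )
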