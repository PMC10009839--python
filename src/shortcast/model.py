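"""Per-IG gradient-boosted forecasting of the shortage impact score.

One regressor per interchangeable group, trained on the lagged feature
table under blocked (expanding-window) time-series cross-validation: split
k trains on the first ``min_train + k - 1`` months and tests on the next
``test_len``, so every test block strictly follows its training window and
successive splits extend training by exactly one month.  Forecasts are
one-step-ahead — holdout month t is predicted from observed features at
t-1..t-4, since reported shortages are public monthly facts at deployment
time — and clipped to [0, 1], the range of the outcome.

Feature importance is permutation-based (mean MAE increase when a column
is independently shuffled), floored at zero, normalised to percentage
shares, and aggregated both by feature family and by family x lag.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.inspection import permutation_importance as _sk_permutation_importance
from xgboost import XGBRegressor

from .features import FeatureTable

__all__ = [
    "CVSplit",
    "Hyperparams",
    "make_blocked_splits",
    "fit_ig_model",
    "cross_validate_ig",
    "forecast_holdout",
    "permutation_importance",
    "aggregate_importance",
]


@dataclass(frozen=True)
class CVSplit:
    """One expanding-window resample: train months strictly before test months."""

    split_id: int
    train_months: tuple[str, ...]
    test_months: tuple[str, ...]

    def __post_init__(self) -> None:
        last_train = max(pd.Period(m, freq="M") for m in self.train_months)
        first_test = min(pd.Period(m, freq="M") for m in self.test_months)
        if not last_train < first_test:
            raise ValueError(f"split {self.split_id}: training window overlaps test block")


@dataclass(frozen=True)
class Hyperparams:
    """Boosted-tree settings (defaults; the reference analysis reports none)."""

    n_estimators: int = 300
    max_depth: int = 4
    learning_rate: float = 0.1
    subsample: float = 0.9

    def regressor(self, seed: int) -> XGBRegressor:
        return XGBRegressor(
            n_estimators=self.n_estimators,
            max_depth=self.max_depth,
            learning_rate=self.learning_rate,
            subsample=self.subsample,
            random_state=seed,
            n_jobs=1,
            verbosity=0,
        )


def make_blocked_splits(
    months, min_train: int = 12, test_len: int = 1
) -> list[CVSplit]:
    """Expanding-window blocked splits over a contiguous month range.

    Split k trains on the first ``min_train + k - 1`` months and tests on
    the following ``test_len``; a 48-month range with defaults yields
    exactly 36 resamples.
    """
    months = [str(pd.Period(m, freq="M")) for m in months]
    if len(months) < min_train + test_len:
        raise ValueError(
            f"need at least {min_train + test_len} months for one split, have {len(months)}"
        )
    splits = []
    k = 0
    while min_train + k + test_len <= len(months):
        n_train = min_train + k
        splits.append(
            CVSplit(
                split_id=k + 1,
                train_months=tuple(months[:n_train]),
                test_months=tuple(months[n_train : n_train + test_len]),
            )
        )
        k += 1
    return splits


def _xy(table: pd.DataFrame, months) -> tuple[pd.DataFrame, pd.Series]:
    rows = table.loc[table.index.intersection(list(months))]
    return rows.drop(columns=["target"]), rows["target"]


def fit_ig_model(
    table: pd.DataFrame,
    split: CVSplit,
    hyperparams: Hyperparams | None = None,
    seed: int = 0,
) -> tuple[XGBRegressor, pd.DataFrame]:
    """Fit one IG's regressor on a split; return (model, test predictions).

    *table* is one IG's frame from the feature table (``target`` column plus
    lagged predictors, indexed by month).  Predictions are clipped to [0, 1]
    and returned as ForecastRecord rows (month, actual, forecast, phase=cv).
    """
    hp = hyperparams or Hyperparams()
    X_tr, y_tr = _xy(table, split.train_months)
    X_te, y_te = _xy(table, split.test_months)
    if X_tr.empty:
        raise ValueError(f"split {split.split_id}: no training rows in the feature table")
    model = hp.regressor(seed)
    model.fit(X_tr, y_tr)
    preds = pd.DataFrame(
        {
            "month": X_te.index,
            "actual": y_te.to_numpy(),
            "forecast": np.clip(model.predict(X_te), 0.0, 1.0) if len(X_te) else [],
            "phase": "cv",
        }
    )
    return model, preds


def cross_validate_ig(
    table: pd.DataFrame,
    splits: list[CVSplit],
    hyperparams: Hyperparams | None = None,
    seed: int = 0,
) -> pd.DataFrame:
    """Run all resamples for one IG; concatenated cv-phase ForecastRecords."""
    parts = [fit_ig_model(table, s, hyperparams, seed)[1] for s in splits]
    return pd.concat(parts, ignore_index=True)


def forecast_holdout(
    features: FeatureTable,
    holdout_months,
    hyperparams: Hyperparams | None = None,
    seed: int = 0,
) -> tuple[pd.DataFrame, dict[str, XGBRegressor]]:
    """Refit each IG on all pre-holdout months and forecast the holdout.

    One-step-ahead: each holdout month is predicted from its observed
    lagged features.  Returns (records, fitted models); records carry one
    row per IG per holdout month with phase=holdout.
    """
    holdout = [str(pd.Period(m, freq="M")) for m in holdout_months]
    hp = hyperparams or Hyperparams()
    records, models = [], {}
    for ig, table in features.frames.items():
        missing = [m for m in holdout if m not in table.index]
        if missing:
            raise ValueError(f"IG {ig}: no feature rows for holdout month(s) {missing}")
        train_months = [m for m in table.index if m not in holdout]
        X_tr, y_tr = _xy(table, train_months)
        X_ho, y_ho = _xy(table, holdout)
        model = hp.regressor(seed)
        model.fit(X_tr, y_tr)
        models[ig] = model
        records.append(
            pd.DataFrame(
                {
                    "ig_code": ig,
                    "month": X_ho.index,
                    "actual": y_ho.to_numpy(),
                    "forecast": np.clip(model.predict(X_ho), 0.0, 1.0),
                    "phase": "holdout",
                }
            )
        )
    return pd.concat(records, ignore_index=True), models


def permutation_importance(
    model,
    X: pd.DataFrame,
    y: pd.Series,
    n_repeats: int = 5,
    seed: int = 0,
) -> pd.Series:
    """Per-column MAE increase under independent permutation, as % shares.

    Negative increases (noise) are floored at zero before normalising; if
    nothing matters (zero total increase) the shares are uniform.
    """
    result = _sk_permutation_importance(
        model, X, y,
        scoring="neg_mean_absolute_error",
        n_repeats=n_repeats,
        random_state=seed,
    )
    inc = np.maximum(result.importances_mean, 0.0)
    total = inc.sum()
    if total <= 0:
        warnings.warn(
            "no column permutation degraded the model; importance shares are uniform",
            RuntimeWarning,
            stacklevel=2,
        )
        shares = np.full(len(X.columns), 100.0 / len(X.columns))
    else:
        shares = inc / total * 100.0
    return pd.Series(shares, index=X.columns, name="share")


def aggregate_importance(
    shares: pd.Series, schema: pd.DataFrame, ig: str
) -> tuple[pd.Series, pd.DataFrame]:
    """Aggregate one IG's column shares by family and by family x lag."""
    meta = schema[schema["ig_code"] == ig].set_index("column")
    df = pd.DataFrame({"share": shares})
    df["family"] = meta["family"].reindex(df.index)
    df["lag"] = meta["lag"].reindex(df.index)
    by_family = df.groupby("family")["share"].sum().sort_values(ascending=False)
    by_lag = df.pivot_table(index="family", columns="lag", values="share", aggfunc="sum").fillna(0.0)
    return by_family, by_lag


def importance_across_igs(
    models: dict[str, object],
    features: FeatureTable,
    eval_months,
    n_repeats: int = 5,
    seed: int = 0,
) -> tuple[pd.Series, pd.DataFrame]:
    """Equal-weight cross-IG average of family and family-x-lag importance."""
    fam_parts, lag_parts = [], []
    eval_months = [str(pd.Period(m, freq="M")) for m in eval_months]
    for ig, model in models.items():
        X, y = _xy(features.frames[ig], eval_months)
        shares = permutation_importance(model, X, y, n_repeats=n_repeats, seed=seed)
        fam, lag = aggregate_importance(shares, features.schema, ig)
        fam_parts.append(fam)
        lag_parts.append(lag)
    fam_avg = pd.concat(fam_parts, axis=1).fillna(0.0).mean(axis=1).sort_values(ascending=False)
    lag_avg = (
        pd.concat(lag_parts).groupby(level=0).mean().fillna(0.0)
    )
    return fam_avg.rename("share"), lag_avg
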