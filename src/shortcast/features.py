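"""Per-IG monthly feature table for shortage forecasting.

For each interchangeable group (IG) and month the table carries:

* per-DIN demand aggregates (average DOS per patient, total DOS, quantity
  dispensed, prescription count, one block per component DIN);
* IG-level aggregates (dos, qty, rx, dos per patient);
* the maximum month-to-month change in the within-IG DIN shares, by
  patients and by DOS (``chg_dist_pat`` / ``chg_dist_dos``);
* the strength of DIN preference as a normalised Gini concentration of the
  shares (``gini_pat`` / ``gini_dos``);
* shortage pressure in neighbouring IGs of the AHFS therapeutic-class
  hierarchy at four distances (same TC, and one/two/three levels up);
* the IG's own shortage impact score.

Every feature is replicated at lags 1-4; only lagged columns are
predictors (the forecast horizon is one month, so nothing contemporaneous
with the outcome enters the model).  Rows whose lag window precedes the
data start are dropped.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "tc_prefix",
    "din_share",
    "max_share_change",
    "gini_preference",
    "neighbour_shortage",
    "assemble_features",
    "FeatureTable",
    "PER_DIN_FAMILIES",
    "IG_FAMILIES",
]

PER_DIN_FAMILIES = ("avgdos_pat.DIN", "tot_dos.DIN", "tot_qty_disp.DIN", "tot_rx.DIN")
IG_FAMILIES = (
    "shortage_impact", "dos", "qty", "rx", "dos_per_pat",
    "chg_dist_dos", "chg_dist_pat", "gini_pat", "gini_dos",
    "shortage_tc", "shortage_tc1", "shortage_tc2", "shortage_tc3",
)


def tc_prefix(tc_code: str, level: int) -> str:
    """AHFS code truncated by *level* trailing segments.

    Level 0 is the full code; for ``"84:04.08.28"`` levels 1-3 give
    ``"84:04.08"``, ``"84:04"`` and ``"84"`` — the progressively broader
    therapeutic classes a pharmacist would fall back to.
    """
    if not 0 <= level <= 3:
        raise ValueError(f"level must be in 0..3, got {level!r}")
    parts = tc_code.replace(":", ".").split(".")
    if level >= len(parts):
        raise ValueError(f"cannot truncate {tc_code!r} by {level} segments")
    head = parts[: len(parts) - level]
    return head[0] if len(head) == 1 else f"{head[0]}:{'.'.join(head[1:])}"


def din_share(
    dispense: pd.DataFrame,
    ig: str,
    when: str,
    basis: str = "patients",
    dins: list[str] | None = None,
) -> pd.Series:
    """Within-IG share of each DIN at month *when*, by patients or DOS."""
    col = {"patients": "tot_patients", "dos": "tot_dos"}[basis]
    rows = dispense[(dispense["ig_code"] == ig) & (dispense["month"].astype(str) == str(when))]
    if dins is None:
        dins = sorted(dispense.loc[dispense["ig_code"] == ig, "din"].unique())
    vals = rows.groupby("din")[col].sum().reindex(dins, fill_value=0.0)
    total = vals.sum()
    if total <= 0:
        return pd.Series(1.0 / len(dins), index=vals.index, name="share")
    return (vals / total).rename("share")


def max_share_change(shares_t: pd.Series, shares_t_minus_1: pd.Series) -> float:
    """Maximum absolute month-to-month share change across DINs, in percent.

    Shares moving from (80, 10, 10)% to (50, 30, 20)% give 30.  DINs absent
    from one month count as share 0 there.
    """
    all_dins = shares_t.index.union(shares_t_minus_1.index)
    a = shares_t.reindex(all_dins, fill_value=0.0)
    b = shares_t_minus_1.reindex(all_dins, fill_value=0.0)
    return float(100.0 * (a - b).abs().max())


def gini_preference(shares) -> float:
    """Normalised Gini concentration of within-IG shares, in [0, 1].

    0 for uniform assignment of DINs to patients, 1 when a single DIN takes
    everything (total preference).  The raw Gini of n shares caps at
    (n-1)/n, so the value is rescaled by n/(n-1) to make the extreme
    attainable; a single-DIN IG returns 0 by convention.
    """
    p = np.asarray(pd.Series(shares).to_numpy(), dtype=float)
    n = p.size
    if n <= 1:
        return 0.0
    total = p.sum()
    if total <= 0:
        return 0.0
    p = np.sort(p / total)
    # mean absolute difference via the sorted closed form
    i = np.arange(1, n + 1)
    g = float(np.sum((2 * i - n - 1) * p) / n)
    return float(np.clip(g * n / (n - 1), 0.0, 1.0))


def _gini_rows(share_matrix: np.ndarray) -> np.ndarray:
    """Row-wise normalised Gini for a (months x dins) share matrix."""
    n = share_matrix.shape[1]
    if n <= 1:
        return np.zeros(share_matrix.shape[0])
    s = np.sort(share_matrix, axis=1)
    i = np.arange(1, n + 1)
    g = ((2 * i - n - 1) * s).sum(axis=1) / n
    return np.clip(g * n / (n - 1), 0.0, 1.0)


def neighbour_shortage(
    ig: str,
    level: int,
    when: str,
    impact: pd.DataFrame,
    catalog: pd.DataFrame,
    dispense: pd.DataFrame,
) -> float:
    """Shortage pressure in the IG's therapeutic-class neighbours.

    DOS-weighted mean of the impact scores of all *other* IGs sharing the
    target's TC prefix at the given level (weights: each neighbour's
    cumulative DOS through the prior month; uniform if no neighbour has
    history yet).  0 when the IG has no neighbours at that level.
    """
    ig_tc = catalog.drop_duplicates("ig_code").set_index("ig_code")["tc_code"]
    target_prefix = tc_prefix(ig_tc[ig], level)
    neighbours = [
        other for other, code in ig_tc.items()
        if other != ig and tc_prefix(code, level) == target_prefix
    ]
    if not neighbours:
        return 0.0
    imp = impact[(impact["month"].astype(str) == str(when)) & impact["ig_code"].isin(neighbours)]
    scores = imp.set_index("ig_code")["score"].reindex(neighbours, fill_value=0.0)
    prior = dispense[dispense["month"].map(lambda m: pd.Period(m, freq="M") < pd.Period(when, freq="M"))]
    w = prior.groupby("ig_code")["tot_dos"].sum().reindex(neighbours, fill_value=0.0)
    if w.sum() <= 0:
        return float(scores.mean())
    return float((scores * w).sum() / w.sum())


@dataclass
class FeatureTable:
    """Per-IG design matrices plus a machine-readable column manifest.

    ``frames`` maps ig_code to a DataFrame indexed by month (string
    ``YYYY-MM``) whose first column is ``target`` (the contemporaneous
    shortage impact score) followed by the lagged predictors.  ``schema``
    describes every predictor column: its feature family (roster name), the
    DIN it belongs to (per-DIN families only) and its lag.
    """

    frames: dict[str, pd.DataFrame]
    schema: pd.DataFrame
    lags: int = 4

    def predictor_columns(self, ig: str) -> list[str]:
        return [c for c in self.frames[ig].columns if c != "target"]

    def to_frame(self) -> pd.DataFrame:
        parts = []
        for ig, df in self.frames.items():
            part = df.reset_index(names="month")
            part.insert(0, "ig_code", ig)
            parts.append(part)
        return pd.concat(parts, ignore_index=True)


def _ig_unlagged(
    ig: str,
    dins: list[str],
    disp_ig: pd.DataFrame,
    impact_scores: pd.Series,
    neighbour_mats: dict[int, pd.Series],
    months: pd.PeriodIndex,
    include_dos_change: bool,
) -> pd.DataFrame:
    def pivot(col: str) -> pd.DataFrame:
        return (
            disp_ig.pivot_table(index="month", columns="din", values=col, aggfunc="sum")
            .reindex(months, fill_value=0)
            .reindex(columns=dins, fill_value=0)
            .fillna(0.0)
        )

    pat, dos = pivot("tot_patients"), pivot("tot_dos")
    qty, rx = pivot("tot_qty_disp"), pivot("tot_rx")
    avgdos = (dos / pat.replace(0, np.nan)).fillna(0.0)

    out = pd.DataFrame(index=months)
    out["shortage_impact"] = impact_scores.reindex(months).to_numpy()
    for din in dins:
        out[f"avgdos_pat.{din}"] = avgdos[din]
        out[f"tot_dos.{din}"] = dos[din]
        out[f"tot_qty_disp.{din}"] = qty[din]
        out[f"tot_rx.{din}"] = rx[din]
    ig_pat = pat.sum(axis=1)
    out["dos"] = dos.sum(axis=1)
    out["qty"] = qty.sum(axis=1)
    out["rx"] = rx.sum(axis=1)
    out["dos_per_pat"] = np.where(ig_pat > 0, out["dos"] / ig_pat.where(ig_pat > 0, 1), 0.0)

    for basis, (mat, name) in {"pat": (pat, "chg_dist_pat"), "dos": (dos, "chg_dist_dos")}.items():
        totals = mat.sum(axis=1).to_numpy()[:, None]
        shares = np.where(totals > 0, mat.to_numpy() / np.where(totals > 0, totals, 1), 1.0 / len(dins))
        diff = np.abs(np.diff(shares, axis=0)).max(axis=1) * 100.0
        out[name] = np.concatenate([[0.0], diff])
        out["gini_" + basis] = _gini_rows(shares)

    for level in range(4):
        col = "shortage_tc" if level == 0 else f"shortage_tc{level}"
        out[col] = neighbour_mats[level].reindex(months).to_numpy()

    if include_dos_change:
        out["chg_dos"] = out["dos"].diff().fillna(0.0)
    return out


def assemble_features(
    dispense: pd.DataFrame,
    impact: pd.DataFrame,
    catalog: pd.DataFrame,
    lags: int = 4,
    include_dos_change: bool = False,
) -> FeatureTable:
    """Build the lagged per-IG feature table from dispensing and impact data.

    Predictors are lags 1..*lags* of every roster feature; the
    contemporaneous impact score is kept only as the ``target`` column.
    The first *lags* months are dropped (incomplete lag window).
    """
    disp = dispense.copy()
    disp["month"] = pd.PeriodIndex(disp["month"].astype(str), freq="M")
    imp = impact.copy()
    imp["month"] = pd.PeriodIndex(imp["month"].astype(str), freq="M")
    months = pd.period_range(disp["month"].min(), disp["month"].max(), freq="M")
    if len(months) < lags + 1:
        raise ValueError(f"need at least {lags + 1} months of data, have {len(months)}")

    ig_tc = catalog.drop_duplicates("ig_code").set_index("ig_code")["tc_code"]
    igs = sorted(ig_tc.index)

    # month x ig matrices of impact scores and cumulative-prior DOS
    imp_mat = (
        imp.pivot_table(index="month", columns="ig_code", values="score", aggfunc="first")
        .reindex(months)
        .reindex(columns=igs)
        .fillna(0.0)
    )
    ig_dos = (
        disp.pivot_table(index="month", columns="ig_code", values="tot_dos", aggfunc="sum")
        .reindex(months, fill_value=0)
        .reindex(columns=igs, fill_value=0)
        .fillna(0.0)
    )
    cum_prior = ig_dos.cumsum().shift(1, fill_value=0.0)

    # neighbour features for all IGs at once, per level
    neighbour: dict[str, dict[int, pd.Series]] = {ig: {} for ig in igs}
    for level in range(4):
        prefixes = ig_tc.map(lambda c: tc_prefix(c, level))
        for _, group in prefixes.groupby(prefixes):
            members = list(group.index)
            W = cum_prior[members].to_numpy()
            S = imp_mat[members].to_numpy()
            wsum, wssum = W.sum(axis=1, keepdims=True), (W * S).sum(axis=1, keepdims=True)
            den = wsum - W
            num = wssum - W * S
            unweighted = (
                (S.sum(axis=1, keepdims=True) - S) / (len(members) - 1)
                if len(members) > 1 else np.zeros_like(S)
            )
            vals = np.where(den > 0, num / np.where(den > 0, den, 1), unweighted)
            if len(members) == 1:
                vals = np.zeros_like(vals)
            for j, ig in enumerate(members):
                neighbour[ig][level] = pd.Series(vals[:, j], index=months)

    frames: dict[str, pd.DataFrame] = {}
    schema_rows = []
    for ig in igs:
        dins = sorted(catalog.loc[catalog["ig_code"] == ig, "din"])
        disp_ig = disp[disp["ig_code"] == ig]
        unlagged = _ig_unlagged(
            ig, dins, disp_ig, imp_mat[ig], neighbour[ig], months, include_dos_change
        )
        cols: dict[str, pd.Series] = {"target": unlagged["shortage_impact"]}
        for col in unlagged.columns:
            for k in range(1, lags + 1):
                cols[f"{col}_lag{k}"] = unlagged[col].shift(k)
        table = pd.DataFrame(cols, index=months).iloc[lags:]
        table.index = table.index.astype(str)
        frames[ig] = table
    # per-DIN columns differ per IG -> one manifest row per (ig, column)
    for ig, table in frames.items():
        for col in table.columns:
            if col == "target":
                continue
            base, lag = col.rsplit("_lag", 1)
            if "." in base:
                fam_stem, din = base.split(".", 1)
                family = f"{fam_stem}.DIN"
            else:
                family, din = base, ""
            schema_rows.append({"ig_code": ig, "column": col, "family": family, "din": din, "lag": int(lag)})
    schema = pd.DataFrame(schema_rows, columns=["ig_code", "column", "family", "din", "lag"])
    return FeatureTable(frames=frames, schema=schema, lags=lags)
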