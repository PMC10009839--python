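"""Monthly shortage impact score per interchangeable group (IG).

The score for an IG in a month is

    score(ig, t) = sum over component DINs d of  w_d(t) * u_d(t)

where ``w_d`` is the DIN's share of the IG's historical days of supply
(cumulative from the start of the series through month t-1) and ``u_d`` is
the fraction of the DIN's pack listings unavailable that month, with each
listing's unavailability measured as the fraction of days of the month it
lies inside a resolved shortage interval (overlapping intervals counted
once).  All pack sizes of a DIN are treated as equally important to the
pharmacies.  The score lives in [0, 1]: 0 when every pack of every DIN is
available, 1 when nothing in the IG is.

Scores are aggregated across all pharmacies jointly — a reported shortage
makes the product equally unavailable to every pharmacy placing orders.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .months import Month, month, overlap_days

__all__ = [
    "dos_weights",
    "pack_unavailability",
    "impact",
    "impact_series",
]


def _cumulative_dos(dispense: pd.DataFrame, ig: str, upto: Month) -> pd.Series:
    """Cumulative DOS per DIN of *ig* over months strictly before *upto*."""
    rows = dispense[dispense["ig_code"] == ig]
    mask = rows["month"].map(lambda m: month(m) < upto)
    return rows[mask].groupby("din")["tot_dos"].sum()


def dos_weights(
    dispense: pd.DataFrame, ig: str, when: str | Month, catalog: pd.DataFrame
) -> pd.Series:
    """Historical-DOS share of each component DIN of *ig* at month *when*.

    Weights are cumulative DOS from the series start through the prior
    month, normalised over the IG; a DIN holding 40% of past DOS gets
    weight 0.4.  With no history at all the weights are uniform over the
    IG's component DINs.
    """
    dins = catalog.loc[catalog["ig_code"] == ig, "din"]
    if dins.empty:
        raise KeyError(f"unknown IG {ig!r}")
    cum = _cumulative_dos(dispense, ig, month(when)).reindex(dins, fill_value=0.0)
    total = cum.sum()
    if total <= 0:
        return pd.Series(1.0 / len(dins), index=cum.index, name="w")
    return (cum / total).rename("w")


def _merge_spans(spans: list[tuple[pd.Timestamp, pd.Timestamp]]) -> list[tuple[pd.Timestamp, pd.Timestamp]]:
    """Union of closed day intervals (overlaps collapse, so days count once)."""
    merged: list[list[pd.Timestamp]] = []
    for start, end in sorted(spans):
        if merged and start <= merged[-1][1] + pd.Timedelta(days=1):
            merged[-1][1] = max(merged[-1][1], end)
        else:
            merged.append([start, end])
    return [(s, e) for s, e in merged]


def _listing_spans(intervals: pd.DataFrame) -> dict[str, list[tuple[pd.Timestamp, pd.Timestamp]]]:
    spans: dict[str, list[tuple[pd.Timestamp, pd.Timestamp]]] = {}
    for iv in intervals.itertuples(index=False):
        span = (pd.Timestamp(iv.start).normalize(), pd.Timestamp(iv.end).normalize())
        for lid in iv.listing_ids:
            spans.setdefault(lid, []).append(span)
    return {lid: _merge_spans(sp) for lid, sp in spans.items()}


def pack_unavailability(
    din: str,
    when: str | Month,
    intervals: pd.DataFrame,
    packs: pd.DataFrame,
) -> float:
    """Fraction of *din*'s pack listings unavailable during month *when*.

    Mean over the DIN's listings of the fraction of days of the month each
    listing spends inside a shortage interval; days covered by several
    intervals count once.
    """
    m = month(when)
    listings = packs.loc[packs["din"] == din, "listing_id"]
    if listings.empty:
        raise KeyError(f"DIN {din!r} has no pack listings")
    relevant = intervals[intervals["din"] == din] if len(intervals) else intervals
    spans = _listing_spans(relevant) if len(relevant) else {}
    n_days = m.days_in_month
    total = 0.0
    for lid in listings:
        covered = sum(overlap_days(m, s, e) for s, e in spans.get(lid, ()))
        total += covered / n_days
    return total / len(listings)


def impact(
    ig: str,
    when: str | Month,
    dispense: pd.DataFrame,
    intervals: pd.DataFrame,
    packs: pd.DataFrame,
    catalog: pd.DataFrame,
) -> float:
    """Shortage impact score of *ig* at month *when* (in [0, 1])."""
    w = dos_weights(dispense, ig, when, catalog)
    score = sum(
        w[din] * pack_unavailability(din, when, intervals, packs) for din in w.index
    )
    return float(min(1.0, max(0.0, score)))


def impact_series(
    dispense: pd.DataFrame,
    intervals: pd.DataFrame,
    packs: pd.DataFrame,
    catalog: pd.DataFrame,
    months: pd.PeriodIndex,
) -> pd.DataFrame:
    """Monthly impact score for every IG over *months*.

    Returns a tidy frame (ig_code, month, score).  Vectorised over the
    cumulative-DOS bookkeeping; per-listing day coverage is only computed
    for DINs that actually appear in some interval.
    """
    months = pd.PeriodIndex(months, freq="M")
    igs = sorted(catalog["ig_code"].unique())
    din_of_ig = {ig: list(grp["din"]) for ig, grp in catalog.groupby("ig_code")}

    # cumulative DOS per DIN at each month boundary (through t-1)
    disp = dispense.copy()
    disp["month"] = pd.PeriodIndex(disp["month"], freq="M")
    pivot = (
        disp.pivot_table(index="month", columns="din", values="tot_dos", aggfunc="sum")
        .reindex(months, fill_value=0)
        .fillna(0.0)
    )
    cum_prior = pivot.cumsum().shift(1, fill_value=0.0)

    # per-DIN unavailability, sparse in DINs with intervals
    unav: dict[str, np.ndarray] = {}
    if len(intervals):
        spans = _listing_spans(intervals)
        listings_per_din = packs.groupby("din")["listing_id"].apply(list)
        for din in intervals["din"].unique():
            lids = listings_per_din[din]
            cov = np.zeros(len(months))
            for lid in lids:
                for s, e in spans.get(lid, ()):
                    cov += np.array(
                        [overlap_days(m, s, e) / m.days_in_month for m in months]
                    )
            unav[din] = cov / len(lids)

    rows = []
    for ig in igs:
        dins = din_of_ig[ig]
        cum = cum_prior.reindex(columns=dins, fill_value=0.0)[dins].to_numpy()  # (months, dins)
        totals = cum.sum(axis=1)
        w = np.where(
            totals[:, None] > 0, cum / np.where(totals[:, None] > 0, totals[:, None], 1.0),
            1.0 / len(dins),
        )
        u = np.stack(
            [unav.get(din, np.zeros(len(months))) for din in dins], axis=1
        )  # (months, dins)
        scores = np.clip((w * u).sum(axis=1), 0.0, 1.0)
        rows.append(pd.DataFrame({"ig_code": ig, "month": [str(m) for m in months], "score": scores}))
    return pd.concat(rows, ignore_index=True)
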