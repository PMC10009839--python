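"""Independent brute-force oracles the implementation is checked against.

Everything here recomputes quantities from first principles by explicit
enumeration — per-day availability scans, O(n^2) pairwise sums, raw
TP/FP/FN/TN tallies — and deliberately shares no code with the package.
"""

import numpy as np
import pandas as pd


def daily_impact_oracle(ig, month_str, dispense, intervals, packs, catalog):
    """Impact score by enumerating every (listing, day) availability flag."""
    m = pd.Period(month_str, freq="M")
    days = pd.date_range(m.start_time.normalize(), m.end_time.normalize(), freq="D")
    dins = [r["din"] for _, r in catalog.iterrows() if r["ig_code"] == ig]

    # historical-DOS weights, summed row by row
    cum = {d: 0.0 for d in dins}
    for _, row in dispense.iterrows():
        if row["ig_code"] == ig and pd.Period(row["month"], freq="M") < m:
            cum[row["din"]] += row["tot_dos"]
    total = sum(cum.values())
    weights = (
        {d: cum[d] / total for d in dins} if total > 0 else {d: 1.0 / len(dins) for d in dins}
    )

    daily_scores = []
    for day in days:
        score = 0.0
        for din in dins:
            listings = [r["listing_id"] for _, r in packs.iterrows() if r["din"] == din]
            down = 0
            for lid in listings:
                unavailable = False
                for _, iv in intervals.iterrows():
                    if (
                        iv["din"] == din
                        and lid in iv["listing_ids"]
                        and pd.Timestamp(iv["start"]).normalize() <= day <= pd.Timestamp(iv["end"]).normalize()
                    ):
                        unavailable = True
                if unavailable:
                    down += 1
            score += weights[din] * down / len(listings)
        daily_scores.append(score)
    return float(np.mean(daily_scores))


def gini_pairwise_oracle(shares):
    """Normalised Gini via the O(n^2) pairwise-difference definition."""
    p = np.asarray(shares, dtype=float)
    n = p.size
    if n <= 1 or p.sum() <= 0:
        return 0.0
    diff_sum = sum(abs(p[i] - p[j]) for i in range(n) for j in range(n))
    g = diff_sum / (2 * n * p.sum())
    return g * n / (n - 1)


def kappa_oracle(matrix):
    """Cohen's kappa from first principles on a contingency matrix."""
    m = np.asarray(matrix, dtype=float)
    n = m.sum()
    p_o = sum(m[i, i] for i in range(m.shape[0])) / n
    p_e = sum(m[i, :].sum() * m[:, i].sum() for i in range(m.shape[0])) / n**2
    return (p_o - p_e) / (1 - p_e)


def class_metric_oracle(matrix, i):
    """(precision, recall, specificity) of class i by raw TP/FP/FN/TN tally."""
    m = np.asarray(matrix, dtype=float)
    k = m.shape[0]
    tp = m[i, i]
    fp = sum(m[j, i] for j in range(k) if j != i)
    fn = sum(m[i, j] for j in range(k) if j != i)
    tn = sum(m[a, b] for a in range(k) for b in range(k) if a != i and b != i)
    prec = tp / (tp + fp) if tp + fp else np.nan
    rec = tp / (tp + fn) if tp + fn else np.nan
    spec = tn / (tn + fp) if tn + fp else np.nan
    return prec, rec, spec


def random_impact_instance(rng):
    """A random tiny world for the daily-oracle equivalence check."""
    n_dins = int(rng.integers(1, 4))
    dins = [f"X{i}" for i in range(n_dins)]
    catalog = pd.DataFrame(
        [{"din": d, "ig_code": "IGX", "tc_code": "10:04.08.12",
          "strength": "5MG", "common_name": d} for d in dins]
    )
    packs = pd.DataFrame(
        [
            {"din": d, "listing_id": f"{d}-P{k}", "pack_size": int(rng.choice([30, 100, 500]))}
            for d in dins
            for k in range(int(rng.integers(1, 4)))
        ]
    )
    months = pd.period_range("2020-01", "2020-06", freq="M")
    dispense = pd.DataFrame(
        [
            {"din": d, "ig_code": "IGX", "month": str(m),
             "tot_dos": int(rng.integers(0, 300)), "tot_patients": int(rng.integers(0, 10)),
             "tot_qty_disp": 0, "tot_rx": 0, "avgdos_pat": 0.0}
            for d in dins
            for m in months
        ]
    )
    n_iv = int(rng.integers(0, 5))
    ivs = []
    for _ in range(n_iv):
        din = dins[int(rng.integers(n_dins))]
        lids = [l for l in packs.loc[packs["din"] == din, "listing_id"]]
        chosen = frozenset(rng.choice(lids, size=int(rng.integers(1, len(lids) + 1)), replace=False))
        start = pd.Timestamp("2020-01-01") + pd.Timedelta(days=int(rng.integers(0, 150)))
        end = start + pd.Timedelta(days=int(rng.integers(0, 90)))
        ivs.append({"din": din, "listing_ids": chosen, "start": start, "end": end})
    intervals = pd.DataFrame(ivs, columns=["din", "listing_ids", "start", "end"])
    target_month = str(months[int(rng.integers(2, len(months)))])
    return catalog, packs, dispense, intervals, target_month
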