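"""Seeded generator for a synthetic pharmacy world.

Emits the three tables the shortage-forecasting analysis consumes — a drug
catalog with an interchangeable-group (IG) and AHFS therapeutic-class (TC)
hierarchy, monthly dispensing aggregates per DIN, and raw shortage reports
with free-text pack sizes and configurable date defects — plus a latent-truth
ledger of the shortage schedule that actually drove the demand process, so
downstream cleaning and scoring can be validated against ground truth.

The demand process encodes the stylised facts the real data shows around
shortages: pharmacists concentrate dispensing on a preferred DIN within each
IG (Dirichlet-distributed shares, drifting slowly), patient share shifts away
from a DIN while its packs are unavailable, days of supply per patient drops
during large shortages (rationing), and dispensing carries a 12-month
seasonal cycle.  Demand responds to shortages with a one-month lag.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .config import ConfigError, SimConfig

__all__ = [
    "SimWorld",
    "generate_catalog",
    "generate_dispensing",
    "generate_shortage_reports",
    "generate_latent_truth",
    "simulate_world",
]

_PACK_SIZE_POOL = np.array([30, 50, 60, 90, 100, 120, 250, 500])
_NAME_STEMS = (
    "TELMISARTAN", "IRBESARTAN", "INDAPAMIDE", "SPIRONOLACTONE", "NAPROXEN",
    "METHOTREXATE", "AMLODIPINE", "METFORMIN", "ATORVASTATIN", "RAMIPRIL",
    "SERTRALINE", "CITALOPRAM", "LEVOTHYROXINE", "OMEPRAZOLE", "GABAPENTIN",
)
_BASE_DPP = 30.0  # days of supply per patient on a typical maintenance script

# independent child RNG streams of the config seed
_STREAM_CATALOG, _STREAM_SCHEDULE, _STREAM_DISPENSE, _STREAM_REPORTS = range(4)


def _rng(config: SimConfig, stream: int) -> np.random.Generator:
    return np.random.default_rng([config.seed, stream])


# ---------------------------------------------------------------------------
# catalog
# ---------------------------------------------------------------------------

def generate_catalog(config: SimConfig) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Generate the drug catalog and the per-DIN pack listings.

    Returns ``(catalog, packs)``: one catalog row per DIN with its IG and
    4-level AHFS-style TC code (``"AA:BB.CC.DD"``), and one pack row per
    listing.  TC leaf codes are drawn from a pool smaller than the number of
    IGs, so sibling IGs exist at every hierarchy level (different dosage
    forms of one molecule genuinely share a TC); pack sizes are unique
    within a DIN so the latent shortage schedule stays recoverable from the
    rendered reports.
    """
    rng = _rng(config, _STREAM_CATALOG)

    # hierarchical TC pool: level-1 roots -> level-2 -> level-3 -> leaves
    n_l1 = max(2, -(-config.n_igs // 16))
    leaves: list[str] = []
    l1_codes = rng.choice(np.arange(4, 95), size=n_l1, replace=False)
    for a in sorted(l1_codes):
        for b in sorted(rng.choice(np.arange(1, 100), size=rng.integers(2, 5), replace=False)):
            for c in sorted(rng.choice(np.arange(1, 100), size=rng.integers(2, 4), replace=False)):
                for d in sorted(rng.choice(np.arange(1, 100), size=rng.integers(1, 4), replace=False)):
                    leaves.append(f"{a:02d}:{b:02d}.{c:02d}.{d:02d}")

    ig_leaves = rng.choice(len(leaves), size=config.n_igs, replace=True)
    if config.n_igs >= 2:
        # guarantee at least one pair of sibling IGs sharing every prefix level
        ig_leaves[1] = ig_leaves[0]

    cat_rows, pack_rows = [], []
    din_counter = 0
    lo_d, hi_d = config.dins_per_ig
    lo_p, hi_p = config.packs_per_din
    for i in range(config.n_igs):
        ig_code = f"IG{i:04d}"
        tc_code = leaves[ig_leaves[i]]
        stem = _NAME_STEMS[i % len(_NAME_STEMS)]
        strength = f"{int(rng.choice([5, 10, 25, 40, 50, 80, 100]))}MG"
        n_dins = int(rng.integers(lo_d, hi_d + 1))
        for _ in range(n_dins):
            din = f"D{din_counter:06d}"
            din_counter += 1
            cat_rows.append(
                {"din": din, "ig_code": ig_code, "tc_code": tc_code,
                 "strength": strength, "common_name": f"{stem} {strength}"}
            )
            n_packs = int(rng.integers(lo_p, hi_p + 1))
            sizes = rng.choice(_PACK_SIZE_POOL, size=n_packs, replace=False)
            for k, size in enumerate(sorted(int(s) for s in sizes)):
                pack_rows.append(
                    {"din": din, "listing_id": f"{din}-P{k}", "pack_size": size}
                )
    return pd.DataFrame(cat_rows), pd.DataFrame(pack_rows)


# ---------------------------------------------------------------------------
# latent shortage schedule
# ---------------------------------------------------------------------------

def _tc_parent(tc_code: str) -> str:
    parts = tc_code.replace(":", ".").split(".")
    head = parts[:-1]
    return head[0] if len(head) == 1 else f"{head[0]}:{'.'.join(head[1:])}"


def _draw_schedule(catalog: pd.DataFrame, packs: pd.DataFrame, config: SimConfig) -> pd.DataFrame:
    """Draw the latent shortage schedule (the ground-truth ledger).

    Each pack listing faces a monthly shortage hazard; durations are
    1 + Geometric(p) months, aligned to month boundaries unless
    ``day_level_dates`` is set.  With probability ``tc_correlation`` an event
    propagates to a random listing of a sibling IG under the same TC parent,
    with the same interval.
    """
    rng = _rng(config, _STREAM_SCHEDULE)
    months = config.month_index
    n_months = len(months)

    din_ig = catalog.set_index("din")["ig_code"]
    ig_tc = catalog.drop_duplicates("ig_code").set_index("ig_code")["tc_code"]
    parent_of = ig_tc.map(_tc_parent)
    siblings: dict[str, list[str]] = {}
    for ig, par in parent_of.items():
        siblings.setdefault(par, []).append(ig)
    listings_by_ig: dict[str, pd.DataFrame] = {
        ig: grp for ig, grp in packs.assign(ig_code=packs["din"].map(din_ig)).groupby("ig_code")
    }

    def _dates(m0: int, m1: int) -> tuple[pd.Timestamp, pd.Timestamp]:
        start_m, end_m = months[m0], months[m1]
        if config.day_level_dates:
            s_day = int(rng.integers(1, start_m.days_in_month + 1))
            e_lo = s_day if m0 == m1 else 1
            e_day = int(rng.integers(e_lo, end_m.days_in_month + 1))
            return (
                pd.Timestamp(start_m.start_time.date()) + pd.Timedelta(days=s_day - 1),
                pd.Timestamp(end_m.start_time.date()) + pd.Timedelta(days=e_day - 1),
            )
        return pd.Timestamp(start_m.start_time.date()), pd.Timestamp(end_m.end_time.date())

    rows = []
    event_id = 0
    for row in packs.itertuples(index=False):
        ig = din_ig[row.din]
        m = 0
        while m < n_months:
            if rng.random() < config.shortage_rate:
                duration = 1 + int(rng.geometric(config.shortage_duration_p))
                m_end = min(m + duration - 1, n_months - 1)
                start, end = _dates(m, m_end)
                rows.append(
                    {"event_id": f"E{event_id:05d}", "din": row.din, "ig_code": ig,
                     "listing_id": row.listing_id, "pack_size": row.pack_size,
                     "start_month": str(months[m]), "end_month": str(months[m_end]),
                     "start_date": start, "end_date": end}
                )
                event_id += 1
                sibs = [s for s in siblings[parent_of[ig]] if s != ig]
                if sibs and rng.random() < config.tc_correlation:
                    sib = sibs[int(rng.integers(len(sibs)))]
                    sib_listings = listings_by_ig[sib]
                    pick = sib_listings.iloc[int(rng.integers(len(sib_listings)))]
                    rows.append(
                        {"event_id": f"E{event_id:05d}", "din": pick["din"], "ig_code": sib,
                         "listing_id": pick["listing_id"], "pack_size": int(pick["pack_size"]),
                         "start_month": str(months[m]), "end_month": str(months[m_end]),
                         "start_date": start, "end_date": end}
                    )
                    event_id += 1
                m = m_end + 2  # at least one clear month between events on a listing
            else:
                m += 1
    cols = ["event_id", "din", "ig_code", "listing_id", "pack_size",
            "start_month", "end_month", "start_date", "end_date"]
    return pd.DataFrame(rows, columns=cols)


def generate_latent_truth(catalog: pd.DataFrame, packs: pd.DataFrame, config: SimConfig) -> pd.DataFrame:
    """The ground-truth shortage schedule (an explicit artifact for testing)."""
    return _draw_schedule(catalog, packs, config)


def _unavailability_matrix(
    schedule: pd.DataFrame, packs: pd.DataFrame, config: SimConfig
) -> dict[str, np.ndarray]:
    """Per-DIN array over the month index of the unavailable pack fraction."""
    months = config.month_index
    n_months = len(months)
    month_pos = {m: i for i, m in enumerate(months)}

    listing_cov: dict[str, np.ndarray] = {}
    for ev in schedule.itertuples(index=False):
        cov = listing_cov.setdefault(ev.listing_id, np.zeros(n_months))
        m0 = month_pos[pd.Period(ev.start_month, freq="M")]
        m1 = month_pos[pd.Period(ev.end_month, freq="M")]
        for mi in range(m0, m1 + 1):
            m = months[mi]
            lo = max(pd.Timestamp(m.start_time.date()), ev.start_date)
            hi = min(pd.Timestamp(m.end_time.date()).normalize(), ev.end_date)
            frac = max(0.0, ((hi - lo).days + 1) / m.days_in_month)
            cov[mi] = min(1.0, cov[mi] + frac)

    unav: dict[str, np.ndarray] = {}
    for din, grp in packs.groupby("din", sort=True):
        arrs = [listing_cov.get(lid, None) for lid in grp["listing_id"]]
        present = [a for a in arrs if a is not None]
        if not present:
            unav[din] = np.zeros(n_months)
        else:
            total = np.zeros(n_months)
            for a in arrs:
                if a is not None:
                    total += a
            unav[din] = total / len(grp)
    return unav


# ---------------------------------------------------------------------------
# dispensing
# ---------------------------------------------------------------------------

def generate_dispensing(
    catalog: pd.DataFrame, packs: pd.DataFrame, config: SimConfig
) -> pd.DataFrame:
    """Generate monthly dispensing aggregates per DIN.

    One row per DIN per month with total days of supply (DOS), patient
    count, quantity dispensed, prescription count and average DOS per
    patient.  The latent shortage schedule is redrawn internally from the
    seed (the same schedule ``generate_shortage_reports`` renders), so
    demand responds to the very shortages the reports describe.
    """
    schedule = _draw_schedule(catalog, packs, config)
    return _dispensing_from_schedule(catalog, packs, schedule, config)


def _dispensing_from_schedule(
    catalog: pd.DataFrame, packs: pd.DataFrame, schedule: pd.DataFrame, config: SimConfig
) -> pd.DataFrame:
    rng = _rng(config, _STREAM_DISPENSE)
    months = config.month_index
    n_months = len(months)
    unav = _unavailability_matrix(schedule, packs, config)

    frames = []
    for ig_code, grp in catalog.groupby("ig_code", sort=True):
        dins = list(grp["din"])
        n = len(dins)
        base_patients = config.n_patients_scale * rng.lognormal(0.0, 0.5)
        phase = rng.integers(0, 12)
        qty_factor = rng.lognormal(0.0, 0.3, size=n)  # units dispensed per DOS day
        shares = rng.dirichlet(np.full(n, config.preference_concentration))
        unav_d = np.stack([unav[d] for d in dins])  # (n, months)

        pat = np.zeros((n, n_months), dtype=int)
        dos = np.zeros((n, n_months), dtype=int)
        qty = np.zeros((n, n_months), dtype=int)
        rx = np.zeros((n, n_months), dtype=int)
        for t in range(n_months):
            # slow random walk on the preference simplex
            shares = shares * np.exp(rng.normal(0.0, config.share_walk_sigma, size=n))
            shares = shares / shares.sum()
            lag_unav = unav_d[:, t - 1] if t > 0 else np.zeros(n)
            eff = shares * (1.0 - config.substitution_strength * lag_unav)
            if eff.sum() <= 0:
                eff = shares.copy()
            eff = eff / eff.sum()
            season = 1.0 + config.seasonal_amplitude * np.sin(2 * np.pi * (t + phase) / 12.0)
            total_pat = base_patients * season * rng.lognormal(0.0, 0.05)
            p = rng.poisson(eff * total_pat)
            dpp = np.maximum(
                1.0, _BASE_DPP * (1.0 - config.dos_drop * lag_unav) * rng.lognormal(0.0, 0.1, size=n)
            )
            d = np.where(p > 0, np.round(p * dpp).astype(int), 0)
            d = np.maximum(d, p)  # at least one day of supply per patient
            pat[:, t] = p
            dos[:, t] = d
            qty[:, t] = np.round(d * qty_factor).astype(int)
            rx[:, t] = np.round(p * rng.uniform(1.0, 1.5, size=n)).astype(int)

        frames.append(
            pd.DataFrame(
                {
                    "din": np.repeat(dins, n_months),
                    "ig_code": ig_code,
                    "month": np.tile([str(m) for m in months], n),
                    "tot_dos": dos.reshape(-1),
                    "tot_patients": pat.reshape(-1),
                    "tot_qty_disp": qty.reshape(-1),
                    "tot_rx": rx.reshape(-1),
                }
            )
        )
    out = pd.concat(frames, ignore_index=True)
    out["avgdos_pat"] = np.where(out["tot_patients"] > 0, out["tot_dos"] / out["tot_patients"], 0.0)
    return out


# ---------------------------------------------------------------------------
# shortage reports
# ---------------------------------------------------------------------------

def generate_shortage_reports(
    catalog: pd.DataFrame, packs: pd.DataFrame, config: SimConfig
) -> pd.DataFrame:
    """Render the latent schedule as raw shortage reports.

    Every latent event becomes one status-``actual`` report with its pack
    size rendered through a random free-text dialect template; date defects
    (blanked actual dates, inverted start/end) are injected at the
    configured rates.  Spurious ``anticipated``/``avoided`` reports — noise
    a status filter must remove — are added on top and never appear in the
    latent-truth ledger.
    """
    schedule = _draw_schedule(catalog, packs, config)
    return _reports_from_schedule(schedule, packs, config)


def _reports_from_schedule(
    schedule: pd.DataFrame, packs: pd.DataFrame, config: SimConfig
) -> pd.DataFrame:
    rng = _rng(config, _STREAM_REPORTS)
    rows = []
    for ev in schedule.itertuples(index=False):
        text = rng.choice(config.text_dialects).format(n=ev.pack_size)
        anticipated = ev.start_date - pd.Timedelta(days=int(rng.integers(3, 45)))
        report = anticipated - pd.Timedelta(days=int(rng.integers(0, 10)))
        updated = ev.end_date + pd.Timedelta(days=int(rng.integers(0, 15)))
        a_start: pd.Timestamp | None = ev.start_date
        a_end: pd.Timestamp | None = ev.end_date
        if rng.random() < config.missing_date_rate:
            a_start = None
        if rng.random() < config.missing_date_rate:
            a_end = None
        if a_start is not None and a_end is not None and rng.random() < config.inverted_date_rate:
            a_start, a_end = a_end, a_start
            updated = None  # force the imputed end to stay inverted
        rows.append(
            {"din": ev.din, "pack_size_text": text, "status": "actual",
             "actual_start": a_start, "actual_end": a_end,
             "anticipated_start": anticipated, "report_date": report,
             "updated_date": updated}
        )

    n_spurious = int(rng.binomial(max(len(schedule), 1), config.spurious_report_rate))
    months = config.month_index
    for _ in range(n_spurious):
        pick = packs.iloc[int(rng.integers(len(packs)))]
        m = months[int(rng.integers(len(months)))]
        start = pd.Timestamp(m.start_time.date())
        end = pd.Timestamp(m.end_time.date()).normalize()
        rows.append(
            {"din": pick["din"], "pack_size_text": str(int(pick["pack_size"])),
             "status": str(rng.choice(["anticipated", "avoided"])),
             "actual_start": None, "actual_end": None,
             "anticipated_start": start, "report_date": start - pd.Timedelta(days=7),
             "updated_date": end}
        )
    cols = ["din", "pack_size_text", "status", "actual_start", "actual_end",
            "anticipated_start", "report_date", "updated_date"]
    out = pd.DataFrame(rows, columns=cols)
    for c in ["actual_start", "actual_end", "anticipated_start", "report_date", "updated_date"]:
        out[c] = pd.to_datetime(out[c])
    return out


# ---------------------------------------------------------------------------
# one-call world
# ---------------------------------------------------------------------------

@dataclass
class SimWorld:
    """All five synthetic tables plus the config that produced them."""

    config: SimConfig
    catalog: pd.DataFrame
    packs: pd.DataFrame
    dispense: pd.DataFrame
    reports: pd.DataFrame
    latent: pd.DataFrame

    def write(self, out_dir: str | Path) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        self.catalog.to_csv(out / "catalog.csv", index=False)
        self.packs.to_csv(out / "packs.csv", index=False)
        self.dispense.to_csv(out / "dispense.csv", index=False)
        reports = self.reports.copy()
        for c in ["actual_start", "actual_end", "anticipated_start", "report_date", "updated_date"]:
            reports[c] = reports[c].dt.strftime("%Y-%m-%d")
        reports.to_csv(out / "shortage_reports.csv", index=False)
        latent = self.latent.copy()
        for c in ["start_date", "end_date"]:
            latent[c] = pd.to_datetime(latent[c]).dt.strftime("%Y-%m-%d")
        latent.to_csv(out / "latent_truth.csv", index=False)


def simulate_world(config: SimConfig) -> SimWorld:
    """Generate catalog, packs, dispensing, shortage reports and latent truth.

    Drawing the latent schedule once and feeding it to both the dispensing
    and report renderers; identical to calling the three generators
    separately (they re-derive the same schedule from the seed).
    """
    catalog, packs = generate_catalog(config)
    schedule = _draw_schedule(catalog, packs, config)
    dispense = _dispensing_from_schedule(catalog, packs, schedule, config)
    reports = _reports_from_schedule(schedule, packs, config)
    return SimWorld(config, catalog, packs, dispense, reports, schedule)
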