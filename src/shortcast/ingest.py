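"""Cleaning of raw shortage reports into resolved shortage intervals.

Raw shortage-report exports carry three kinds of defect this module
repairs or removes:

* irrelevant statuses — only ``actual`` (and resolved) shortages matter for
  outcome construction; ``anticipated`` and ``avoided`` reports are dropped;
* missing or inverted dates — start dates are imputed through the cascade
  actual start -> anticipated start -> entry date, end dates through
  actual end -> last-updated date; records whose dates remain missing or
  intractable (start after end) are removed and counted;
* free-text pack sizes — the reported text ("100 Bottle", "100 BTL", ...)
  is parsed to its numeric components and matched against the distributor
  catalog's numeric pack listings; when no listing matches, the DIN is
  assumed shorted in all of its pack sizes.

Records filed before mandatory reporting began (March 2017 by default) are
excluded.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass
from pathlib import Path

import pandas as pd

__all__ = [
    "CleaningLog",
    "filter_reports",
    "impute_dates",
    "parse_pack_text",
    "match_packs",
    "build_intervals",
]

MANDATORY_REPORTING_START = pd.Timestamp("2017-03-01")

_DIGITS = re.compile(r"\d+")


@dataclass
class CleaningLog:
    """Counts of what cleaning did, so removals are reported, never silent."""

    n_input: int = 0
    n_non_actual: int = 0
    n_before_window: int = 0
    n_rejected_dates: int = 0
    n_all_pack_fallback: int = 0
    n_resolved: int = 0

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.__dict__, indent=2) + "\n")


def impute_dates(report: pd.Series) -> tuple[pd.Timestamp, pd.Timestamp] | None:
    """Impute (start, end) for one report, or ``None`` to reject it.

    Start is the first present of actual start, anticipated start, entry
    date; end the first present of actual end, last-updated date.  Returns
    ``None`` when the end remains missing or the start falls after the end
    (the record is intractable and must be removed, with the removal
    counted by the caller).
    """
    start = report.get("actual_start")
    if pd.isna(start):
        start = report.get("anticipated_start")
    if pd.isna(start):
        start = report.get("report_date")
    end = report.get("actual_end")
    if pd.isna(end):
        end = report.get("updated_date")
    if pd.isna(start) or pd.isna(end):
        return None
    start, end = pd.Timestamp(start), pd.Timestamp(end)
    if start > end:
        return None
    return start, end


def filter_reports(
    reports: pd.DataFrame, earliest: pd.Timestamp | str = MANDATORY_REPORTING_START
) -> pd.DataFrame:
    """Keep only status-``actual`` reports whose imputed start is on/after *earliest*."""
    earliest = pd.Timestamp(earliest)
    if reports.empty:
        return reports.copy()
    actual = reports[reports["status"] == "actual"]
    keep = []
    for idx, row in actual.iterrows():
        imputed = impute_dates(row)
        start = imputed[0] if imputed is not None else row.get("report_date")
        if pd.notna(start) and pd.Timestamp(start) >= earliest:
            keep.append(idx)
    return actual.loc[keep].copy()


def parse_pack_text(text) -> list[int]:
    """All maximal digit runs in the free-form pack text, in order."""
    if text is None or (isinstance(text, float) and pd.isna(text)):
        return []
    return [int(run) for run in _DIGITS.findall(str(text))]


def match_packs(din: str, numbers: list[int], packs: pd.DataFrame) -> frozenset[str]:
    """Resolve parsed pack numbers to catalog listing ids for *din*.

    A number matches every listing of the DIN with that pack size (distinct
    manufacturers sharing a size are equally affected).  Multi-number texts
    ("10 x 50 Blister") additionally try the product of all numbers.  An
    empty match — including unparseable text — falls back to all listings of
    the DIN: an ambiguous report is read as the DIN being short in every
    pack size.
    """
    din_packs = packs[packs["din"] == din]
    if din_packs.empty:
        raise KeyError(f"DIN {din!r} has no pack listings in the catalog")
    hit = din_packs[din_packs["pack_size"].isin(numbers)]
    if hit.empty and len(numbers) > 1:
        product = 1
        for n in numbers:
            product *= n
        hit = din_packs[din_packs["pack_size"] == product]
    if hit.empty:
        hit = din_packs
    return frozenset(hit["listing_id"])


def build_intervals(
    reports: pd.DataFrame,
    packs: pd.DataFrame,
    earliest: pd.Timestamp | str = MANDATORY_REPORTING_START,
    clamp_end: pd.Timestamp | str | None = None,
) -> tuple[pd.DataFrame, CleaningLog]:
    """Full cleaning pipeline: filter -> impute -> parse -> match.

    Returns a resolved-shortage table (din, listing_ids, start, end) and the
    cleaning log.  ``clamp_end`` caps open-ended intervals at the last day
    covered by the dispensing data, for reports still open at data pull.
    """
    log = CleaningLog(n_input=len(reports))
    earliest = pd.Timestamp(earliest)
    log.n_non_actual = int((reports["status"] != "actual").sum()) if len(reports) else 0
    actual = reports[reports["status"] == "actual"] if len(reports) else reports

    rows = []
    for _, rep in actual.iterrows():
        imputed = impute_dates(rep)
        if imputed is None:
            log.n_rejected_dates += 1
            continue
        start, end = imputed
        if start < earliest:
            log.n_before_window += 1
            continue
        if clamp_end is not None:
            end = min(end, pd.Timestamp(clamp_end))
            if end < start:
                log.n_rejected_dates += 1
                continue
        numbers = parse_pack_text(rep["pack_size_text"])
        din_packs = packs[packs["din"] == rep["din"]]
        listing_ids = match_packs(rep["din"], numbers, packs)
        direct = din_packs[din_packs["pack_size"].isin(numbers)]
        if direct.empty and not (
            len(numbers) > 1
            and (din_packs["pack_size"] == _product(numbers)).any()
        ):
            log.n_all_pack_fallback += 1
        rows.append({"din": rep["din"], "listing_ids": listing_ids, "start": start, "end": end})

    resolved = pd.DataFrame(rows, columns=["din", "listing_ids", "start", "end"])
    log.n_resolved = len(resolved)
    return resolved, log


def _product(numbers: list[int]) -> int:
    out = 1
    for n in numbers:
        out *= n
    return out


def write_intervals(resolved: pd.DataFrame, path: str | Path) -> None:
    out = resolved.copy()
    out["listing_ids"] = out["listing_ids"].map(lambda s: ";".join(sorted(s)))
    out["start"] = pd.to_datetime(out["start"]).dt.strftime("%Y-%m-%d")
    out["end"] = pd.to_datetime(out["end"]).dt.strftime("%Y-%m-%d")
    out.to_csv(path, index=False)


def read_intervals(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    df["listing_ids"] = df["listing_ids"].map(lambda s: frozenset(str(s).split(";")))
    df["start"] = pd.to_datetime(df["start"])
    df["end"] = pd.to_datetime(df["end"])
    return df
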