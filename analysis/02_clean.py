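"""Clean the raw shortage reports into resolved shortage intervals.

Status filtering (actual only), the date-imputation cascade, free-text
pack-size parsing and catalog matching; removals are counted, never silent.
"""

import pandas as pd

from common import RESULTS, SCRATCH, STUDY_CONFIG, ensure_dirs
from shortcast.ingest import build_intervals, write_intervals

DATE_COLS = ["actual_start", "actual_end", "anticipated_start", "report_date", "updated_date"]


def main() -> None:
    ensure_dirs()
    reports = pd.read_csv(SCRATCH / "data" / "shortage_reports.csv", parse_dates=DATE_COLS)
    packs = pd.read_csv(SCRATCH / "data" / "packs.csv")
    last_day = pd.Timestamp(STUDY_CONFIG.month_index[-1].end_time.date())
    intervals, log = build_intervals(reports, packs, earliest="2017-03-01", clamp_end=last_day)

    write_intervals(intervals, SCRATCH / "shortage_intervals.csv")
    log.to_json(RESULTS / "cleaning_log.json")
    print(f"{log.n_input} raw reports -> {log.n_resolved} resolved intervals")
    print(f"  non-actual removed: {log.n_non_actual}; before window: {log.n_before_window}; "
          f"intractable dates: {log.n_rejected_dates}; all-pack fallbacks: {log.n_all_pack_fallback}")


if __name__ == "__main__":
    main()
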