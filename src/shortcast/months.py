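"""Calendar-month helpers.

All time series in the package run at monthly resolution; months are
``pandas.Period`` objects with freq ``"M"`` internally and ``"YYYY-MM"``
strings at file boundaries.
"""

from __future__ import annotations

from typing import Iterable

import pandas as pd

Month = pd.Period


def month(value: str | pd.Period | pd.Timestamp) -> Month:
    """Coerce a ``"YYYY-MM"`` string, Timestamp or Period to a monthly Period."""
    return pd.Period(value, freq="M")


def month_range(start: str | Month, end: str | Month) -> pd.PeriodIndex:
    """Inclusive range of months from *start* to *end*."""
    return pd.period_range(month(start), month(end), freq="M")


def days_in_month(m: Month) -> int:
    return m.days_in_month


def overlap_days(m: Month, start: pd.Timestamp, end: pd.Timestamp) -> int:
    """Number of days of [start, end] (inclusive) that fall inside month *m*."""
    lo = max(pd.Timestamp(m.start_time.date()), start.normalize())
    hi = min(pd.Timestamp(m.end_time.date()), end.normalize())
    if hi < lo:
        return 0
    return (hi - lo).days + 1


def to_strings(months: Iterable[Month]) -> list[str]:
    return [str(m) for m in months]
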