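"""Calendar-month date arithmetic.

All study windows are anchored on calendar months: adding *n* months keeps
the day-of-month and clips to the end of the target month (Jan 31 + 1 month
is Feb 28/29).  This mirrors how monthly surveillance data requests are
scheduled and is deterministic, unlike "30-day month" conventions.

All intervals in the package are half-open ``[start, end)``.
"""

from __future__ import annotations

import calendar
import datetime as dt

import numpy as np
import pandas as pd

__all__ = ["add_months", "add_months_series", "months_between_at_least"]


def add_months(date: dt.date, months: int) -> dt.date:
    """Return *date* shifted by *months* calendar months, day clipped to month end."""
    month_index = date.month - 1 + months
    year = date.year + month_index // 12
    month = month_index % 12 + 1
    day = min(date.day, calendar.monthrange(year, month)[1])
    return dt.date(year, month, day)


def months_between_at_least(earlier: dt.date, later: dt.date, months: int) -> bool:
    """True iff *later* is at least *months* calendar months after *earlier*."""
    return later >= add_months(earlier, months)


def add_months_series(dates: pd.Series, months: int) -> pd.Series:
    """Vectorised :func:`add_months` for a datetime64 Series."""
    y = dates.dt.year.to_numpy()
    m0 = dates.dt.month.to_numpy() - 1 + months
    year = y + m0 // 12
    month = m0 % 12 + 1
    # days_in_month: vectorised via pandas period arithmetic
    eom = pd.PeriodIndex.from_fields(
        year=year, month=month, freq="M"
    ).days_in_month.to_numpy()
    day = np.minimum(dates.dt.day.to_numpy(), eom)
    out = pd.to_datetime({"year": year, "month": month, "day": day})
    out.index = dates.index
    return out
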