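"""The study window: in-care year, out-of-care window, lag period.

The reconciliation cycle is anchored on four dates::

    in_care_start ──12 mo──> in_care_end ──6 mo──> ooc_end ──lag──> data_request_date

* ``[in_care_start, in_care_end)`` — the "in care" year.  A patient is in
  care iff they have at least one clinic visit AND at least one viral load
  in this interval.
* ``[in_care_end, ooc_end)`` — the out-of-care (OOC) window.  Presence or
  absence of a visit and of a VL here yields the Box A/B/C/D class.
* ``[ooc_end, data_request_date)`` — the lag period, a buffer (≥ 1 calendar
  month) between the end of the OOC window and the data request, absorbing
  lab-reporting delay.  A visit here is a "recent visit" disposition.

All intervals are half-open: an event dated exactly on an interval's end
belongs to the next interval, never to two at once.
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass

from .dates import add_months

__all__ = ["StudyWindow"]


@dataclass(frozen=True)
class StudyWindow:
    in_care_start: dt.date
    in_care_end: dt.date
    ooc_end: dt.date
    data_request_date: dt.date

    def __post_init__(self) -> None:
        if not (
            self.in_care_start
            < self.in_care_end
            < self.ooc_end
            <= self.data_request_date
        ):
            raise ValueError(
                "study window dates must be strictly increasing: "
                f"{self.in_care_start} < {self.in_care_end} < {self.ooc_end} "
                f"<= {self.data_request_date}"
            )
        if self.data_request_date < add_months(self.ooc_end, 1):
            raise ValueError(
                "lag period must be at least one calendar month "
                f"(ooc_end={self.ooc_end}, data_request_date={self.data_request_date})"
            )

    @classmethod
    def from_start(
        cls,
        in_care_start: dt.date,
        *,
        in_care_months: int = 12,
        ooc_months: int = 6,
        lag_months: int = 1,
    ) -> "StudyWindow":
        """Canonical 12-month in-care / 6-month OOC / 1-month lag layout."""
        in_care_end = add_months(in_care_start, in_care_months)
        ooc_end = add_months(in_care_end, ooc_months)
        return cls(
            in_care_start=in_care_start,
            in_care_end=in_care_end,
            ooc_end=ooc_end,
            data_request_date=add_months(ooc_end, lag_months),
        )

    @property
    def upcoming_visit_horizon(self) -> dt.date:
        """End of the window in which a scheduled appointment counts as 'upcoming'
        (3 calendar months after the data request)."""
        return add_months(self.data_request_date, 3)

    def in_care_span_months(self) -> int:
        """Number of whole calendar months in the in-care period."""
        n = 0
        while add_months(self.in_care_start, n + 1) <= self.in_care_end:
            n += 1
        return n

    def to_dict(self) -> dict:
        return {
            "in_care_start": self.in_care_start.isoformat(),
            "in_care_end": self.in_care_end.isoformat(),
            "ooc_end": self.ooc_end.isoformat(),
            "data_request_date": self.data_request_date.isoformat(),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "StudyWindow":
        return cls(**{k: dt.date.fromisoformat(str(d[k])) for k in
                      ("in_care_start", "in_care_end", "ooc_end", "data_request_date")})
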