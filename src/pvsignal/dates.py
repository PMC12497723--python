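"""Partial-precision dates as they appear in spontaneous-reporting extracts.

FAERS date fields (FDA_DT, EVENT_DT, START_DT) are digit strings of length
4 (year), 6 (year-month) or 8 (year-month-day).  Precision must be kept:
a month-precision therapy start cannot anchor a day-resolved onset, but it
can still participate in "most recent report" ordering during
deduplication.
"""

from __future__ import annotations

import datetime
from dataclasses import dataclass

__all__ = ["PartialDate", "parse_partial_date"]

_PRECISIONS = {4: "year", 6: "month", 8: "day"}


@dataclass(frozen=True, order=False)
class PartialDate:
    """A date known to year, month or day precision."""

    raw: str
    precision: str  # "year" | "month" | "day"

    def sort_key(self) -> int:
        """Zero-padded numeric order: best-available-precision comparison.

        ``"202001"`` sorts as 20200100, strictly before ``"20200101"``.
        """
        return int(self.raw.ljust(8, "0"))

    def to_date(self) -> datetime.date | None:
        """Calendar date, or None unless day precision (and a valid date)."""
        if self.precision != "day":
            return None
        try:
            return datetime.date(
                int(self.raw[:4]), int(self.raw[4:6]), int(self.raw[6:8])
            )
        except ValueError:
            return None

    @property
    def year(self) -> int:
        return int(self.raw[:4])

    def __str__(self) -> str:
        return self.raw


def parse_partial_date(value: str | None) -> PartialDate | None:
    """Parse a FAERS date string; non-conforming or empty values give None."""
    if value is None:
        return None
    s = str(value).strip()
    if not s.isdigit():
        return None
    precision = _PRECISIONS.get(len(s))
    if precision is None:
        return None
    return PartialDate(raw=s, precision=precision)
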