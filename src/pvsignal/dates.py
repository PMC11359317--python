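"""Partial-precision dates.

FAERS date fields (FDA_DT, EVENT_DT, START_DT, ...) appear as YYYYMMDD,
YYYYMM or YYYY strings, and are frequently blank or malformed.  Ingestion
keeps every record and attaches an explicit precision instead of dropping
partial dates; downstream stages (e.g. time-to-onset) decide usability.
"""

from __future__ import annotations

import datetime as _dt
import enum
from dataclasses import dataclass

__all__ = ["Precision", "DateWithPrecision", "parse_faers_date"]


class Precision(str, enum.Enum):
    DAY = "day"
    MONTH = "month"
    YEAR = "year"
    MISSING = "missing"


@dataclass(frozen=True)
class DateWithPrecision:
    """An integer-encoded date plus the precision it was reported at.

    ``value`` is YYYYMMDD with zeroed month/day digits for coarser
    precisions (e.g. 20230100 for month precision), and 0 when missing.
    """

    value: int
    precision: Precision

    def __post_init__(self) -> None:
        if self.precision is Precision.DAY:
            # must be a valid calendar date
            self.date  # noqa: B018 - raises if invalid

    @property
    def date(self) -> _dt.date:
        if self.precision is not Precision.DAY:
            raise ValueError(f"no exact calendar date at precision {self.precision.value}")
        y, m, d = self.value // 10000, (self.value // 100) % 100, self.value % 100
        return _dt.date(y, m, d)

    @property
    def is_missing(self) -> bool:
        return self.precision is Precision.MISSING


MISSING_DATE = DateWithPrecision(0, Precision.MISSING)


def parse_faers_date(raw: object) -> DateWithPrecision:
    """Parse a FAERS date string leniently.

    8 digits → day precision, 6 → month, 4 → year; anything else
    (including invalid calendar dates such as 20230230) → missing.
    Never raises.
    """
    if raw is None:
        return MISSING_DATE
    s = str(raw).strip()
    if not s or not s.isdigit():
        return MISSING_DATE
    try:
        if len(s) == 8:
            v = int(s)
            _dt.date(v // 10000, (v // 100) % 100, v % 100)
            return DateWithPrecision(v, Precision.DAY)
        if len(s) == 6:
            y, m = int(s[:4]), int(s[4:])
            if 1 <= m <= 12:
                return DateWithPrecision(y * 10000 + m * 100, Precision.MONTH)
            return MISSING_DATE
        if len(s) == 4:
            return DateWithPrecision(int(s) * 10000, Precision.YEAR)
    except ValueError:
        return MISSING_DATE
    return MISSING_DATE
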