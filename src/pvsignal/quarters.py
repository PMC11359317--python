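"""Calendar quarters as used by FDA quarterly data extracts.

FAERS is distributed as quarterly file packets named by year and quarter
(e.g. ``2017Q4``).  A study window is an inclusive, contiguous span of
quarters; :func:`enumerate_quarters` expands such a span.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from functools import total_ordering

__all__ = ["QuarterLabel", "enumerate_quarters"]

_LABEL_RE = re.compile(r"^(\d{4})[Qq]([1-4])$")


@total_ordering
@dataclass(frozen=True)
class QuarterLabel:
    """A calendar quarter, ordered lexicographically by (year, quarter)."""

    year: int
    quarter: int

    def __post_init__(self) -> None:
        if not 1 <= self.quarter <= 4:
            raise ValueError(f"quarter must be in 1..4, got {self.quarter}")
        if self.year < 1900 or self.year > 2200:
            raise ValueError(f"implausible year {self.year}")

    @classmethod
    def parse(cls, label: str) -> "QuarterLabel":
        m = _LABEL_RE.match(label.strip())
        if m is None:
            raise ValueError(f"malformed quarter label {label!r}; expected YYYYQn")
        return cls(int(m.group(1)), int(m.group(2)))

    def __str__(self) -> str:
        return f"{self.year}Q{self.quarter}"

    def __lt__(self, other: "QuarterLabel") -> bool:
        return (self.year, self.quarter) < (other.year, other.quarter)

    def next(self) -> "QuarterLabel":
        if self.quarter == 4:
            return QuarterLabel(self.year + 1, 1)
        return QuarterLabel(self.year, self.quarter + 1)

    @property
    def file_suffix(self) -> str:
        """Two-digit-year suffix used in FAERS file names, e.g. ``17Q4``."""
        return f"{self.year % 100:02d}Q{self.quarter}"


def enumerate_quarters(
    start: QuarterLabel | str, end: QuarterLabel | str
) -> list[QuarterLabel]:
    """Inclusive ascending list of quarters from *start* to *end*.

    Raises ``ValueError`` if ``start > end``.
    """
    if isinstance(start, str):
        start = QuarterLabel.parse(start)
    if isinstance(end, str):
        end = QuarterLabel.parse(end)
    if start > end:
        raise ValueError(f"start quarter {start} is after end quarter {end}")
    out = [start]
    while out[-1] < end:
        out.append(out[-1].next())
    return out
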