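"""Partial calendar dates as they appear in spontaneous-report databases.

FAERS date fields carry 4-, 6-, or 8-digit tokens (``YYYY``, ``YYYYMM``,
``YYYYMMDD``).  Many records truncate or omit the date entirely, so dates are
modelled as a :class:`PartialDate` that records exactly the components that
were reported.  Only fully specified dates take part in day arithmetic.
"""

from __future__ import annotations

import datetime as _dt
from dataclasses import dataclass
from typing import Optional


@dataclass(frozen=True)
class PartialDate:
    """A calendar date with possibly missing month and day.

    Invariant: ``day`` present implies ``month`` present implies ``year``
    present.  ``raw`` keeps the original token so a file round-trips exactly.
    """

    year: Optional[int] = None
    month: Optional[int] = None
    day: Optional[int] = None
    raw: str = ""

    def __post_init__(self) -> None:
        if self.day is not None and self.month is None:
            raise ValueError("day without month in partial date")
        if self.month is not None and self.year is None:
            raise ValueError("month without year in partial date")
        if self.month is not None and not 1 <= self.month <= 12:
            raise ValueError(f"month out of range: {self.month}")
        if self.day is not None and not 1 <= self.day <= 31:
            raise ValueError(f"day out of range: {self.day}")

    @property
    def is_complete(self) -> bool:
        """True when year, month and day are all present (day arithmetic OK)."""
        return self.day is not None

    @property
    def is_absent(self) -> bool:
        return self.year is None

    def to_date(self) -> _dt.date:
        """Convert to :class:`datetime.date`; requires a complete date."""
        if not self.is_complete:
            raise ValueError(f"partial date {self.raw!r} has no day precision")
        return _dt.date(self.year, self.month, self.day)  # type: ignore[arg-type]

    def token(self) -> str:
        """The original 0-, 4-, 6- or 8-digit token."""
        return self.raw

    def sort_key(self) -> str:
        """Zero-padded 8-character key; absent components sort earliest."""
        y = f"{self.year:04d}" if self.year is not None else "0000"
        m = f"{self.month:02d}" if self.month is not None else "00"
        d = f"{self.day:02d}" if self.day is not None else "00"
        return y + m + d


def parse_date_token(token: object) -> PartialDate:
    """Parse a FAERS date token into a :class:`PartialDate`.

    Accepts 4-digit (year), 6-digit (year+month) and 8-digit (full) tokens.
    Raises ``ValueError`` for anything else non-empty; empty/NA tokens give an
    absent date.
    """
    if token is None:
        return PartialDate(raw="")
    text = str(token).strip()
    if text in ("", "nan", "<NA>", "NA"):
        return PartialDate(raw="")
    if not text.isdigit() or len(text) not in (4, 6, 8):
        raise ValueError(f"malformed date token: {text!r}")
    year = int(text[:4])
    month = int(text[4:6]) if len(text) >= 6 else None
    day = int(text[6:8]) if len(text) == 8 else None
    pd_ = PartialDate(year=year, month=month, day=day, raw=text)
    if pd_.is_complete:
        pd_.to_date()  # validates e.g. Feb 30
    return pd_


def days_between(start: PartialDate, end: PartialDate) -> int:
    """Calendar-day difference ``end - start``; both must be complete."""
    return (end.to_date() - start.to_date()).days
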