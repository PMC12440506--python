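"""2x2 contingency tables for drug-event disproportionality.

For each event term the database is cross-classified against target-drug
exposure:

    =============  ==============  ==================
                   event of        all other events
                   interest
    =============  ==============  ==================
    target drug    a               b
    other drugs    c               d
    =============  ==============  ==================

The counting unit is the unique report-event pair, the convention of
spontaneous-report disproportionality analysis: ``a`` equals the number of
target-drug reports mentioning the term (each report counts once per term),
``a + b`` is the target cohort's total pair count, ``a + c`` the term's total
pair count, and ``n = a+b+c+d`` the database pair total.  A report-level
unit (each report counts once toward ``n`` regardless of how many terms it
lists) is available via ``unit="report"``.

Tables are built at PT level directly from the REAC pairs and at SOC level
after collapsing each report's PTs through the PT -> SOC vocabulary (a
report with three PTs in one SOC contributes a single pair to that SOC).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Iterable, Set, Tuple

import pandas as pd

from .io import PtSocMap, ValidationError


@dataclass(frozen=True)
class ContingencyTable:
    """Counts (a, b, c, d) for one drug-event pair."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError("contingency counts must be nonnegative")
        if self.n == 0:
            raise ValueError("empty contingency table")

    @property
    def n(self) -> int:
        return self.a + self.b + self.c + self.d

    def continuity_corrected(self, k: float = 0.5) -> "Haldane":
        """Haldane-style corrected view (adds *k* to every cell)."""
        return Haldane(self.a + k, self.b + k, self.c + k, self.d + k)


@dataclass(frozen=True)
class Haldane:
    """Continuity-corrected cell values (floats, internal use)."""

    a: float
    b: float
    c: float
    d: float

    @property
    def n(self) -> float:
        return self.a + self.b + self.c + self.d


def _tables_from_pairs(pairs: pd.DataFrame, term_col: str,
                       target_ids: Set[str], unit: str) -> Dict[str, ContingencyTable]:
    is_target = pairs["primaryid"].isin(target_ids)
    if unit == "pair":
        n_target_total = int(is_target.sum())
        n_total = len(pairs)
    elif unit == "report":
        n_target_total = pairs.loc[is_target, "primaryid"].nunique()
        n_total = pairs["primaryid"].nunique()
    else:
        raise ValueError(f"unknown counting unit: {unit!r}")

    a_counts = pairs.loc[is_target, term_col].value_counts()
    all_counts = pairs[term_col].value_counts()

    tables: Dict[str, ContingencyTable] = {}
    for term, total in all_counts.items():
        a = int(a_counts.get(term, 0))
        b = n_target_total - a
        c = int(total) - a
        d = n_total - a - b - c
        tables[term] = ContingencyTable(a=a, b=b, c=c, d=d)
    return tables


def build_pt_tables(events: pd.DataFrame, target_ids: Iterable[str],
                    unit: str = "pair") -> Dict[str, ContingencyTable]:
    """One 2x2 table per preferred term observed anywhere in the database.

    Parameters
    ----------
    events : REAC frame of unique (primaryid, pt) pairs.
    target_ids : primaryids of the target-drug cohort.
    unit : "pair" (default) or "report" — what a single count represents.
    """
    if events.empty:
        raise ValidationError("event set is empty")
    return _tables_from_pairs(events, "pt", set(target_ids), unit)


def build_soc_tables(events: pd.DataFrame, target_ids: Iterable[str],
                     mapping: PtSocMap, unit: str = "pair",
                     ) -> Tuple[Dict[str, ContingencyTable], Set[str]]:
    """2x2 tables at System Organ Class level.

    PTs missing from the vocabulary are excluded from the SOC tables and
    returned as a side set so the caller can report them; they are never
    silently defaulted.

    Returns
    -------
    (tables, unmapped_pts)
    """
    if events.empty:
        raise ValidationError("event set is empty")
    unmapped = mapping.unmapped(events["pt"].unique())
    mapped = events[~events["pt"].isin(unmapped)]
    soc_pairs = (mapped.assign(soc=mapped["pt"].map(mapping.entries))
                       .drop_duplicates(["primaryid", "soc"])
                       [["primaryid", "soc"]])
    if soc_pairs.empty:
        return {}, unmapped
    return _tables_from_pairs(soc_pairs, "soc", set(target_ids), unit), unmapped
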