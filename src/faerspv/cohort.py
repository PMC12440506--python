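"""Target-drug cohort selection and descriptive characteristics.

The analysis cohort is the set of deduplicated reports in which the target
drug (matched by generic or brand name) appears with a given role code —
primary suspect (PS) by default.  The descriptive summary mirrors the layout
pharmacovigilance studies print: counts and percentages by sex, age bin,
country, reporter occupation, serious outcome and report year.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Dict, Iterable, List

import numpy as np
import pandas as pd

from .io import ValidationError

AGE_BIN_LABELS = ("<18", "18-<65", ">=65", "unknown")
OUTCOME_LABELS = {
    "DE": "death",
    "DS": "disability",
    "LT": "life-threatening",
    "HO": "hospitalization",
    "OT": "other",
    "RI": "other",
    "CA": "other",
}
SEX_LABELS = ("male", "female", "unknown")


def pct(count: float, total: int) -> float:
    """Display percentage: 100 * count / total, rounded to 2 decimals."""
    return round(100.0 * count / total, 2)


def select_target_reports(demo: pd.DataFrame, drug: pd.DataFrame,
                          names: Iterable[str], role: str = "PS",
                          substring: bool = False) -> List[str]:
    """Primaryids of reports with >=1 target-drug mention in the given role.

    A mention matches when its drugname *or* active-ingredient string equals
    one of *names* (case-insensitive, trimmed); ``substring=True`` relaxes the
    match to containment, at the cost of catching combination products.
    Each report is returned once, in sorted order.
    """
    names = {str(n).strip().upper() for n in names if str(n).strip()}
    if not names:
        raise ValidationError("target name set is empty")
    mentions = drug[drug["role_code"] == role]
    if substring:
        pattern = "|".join(sorted(map(re.escape, names)))
        hit = (mentions["drugname"].str.contains(pattern, regex=True)
               | mentions["active_ingredient"].str.contains(pattern, regex=True))
    else:
        hit = (mentions["drugname"].isin(names)
               | mentions["active_ingredient"].isin(names))
    ids = set(mentions.loc[hit, "primaryid"]) & set(demo["primaryid"])
    return sorted(ids)


@dataclass
class CohortSummary:
    """Counts and display percentages for one report cohort.

    Every categorical block (sex, age, country, reporter, year) partitions
    the cohort, so its counts sum to ``n``.  Outcome rows are report-level
    flags over the same denominator: a report with several outcome codes is
    counted in each row, one with none is "unknown", so outcome counts need
    not sum to ``n``.
    """

    n: int
    sex: Dict[str, int]
    age: Dict[str, int]
    country: Dict[str, int]
    reporter: Dict[str, int]
    outcomes: Dict[str, int]
    year: Dict[str, int]

    def percentages(self, block: str) -> Dict[str, float]:
        counts: Dict[str, int] = getattr(self, block)
        return {k: pct(v, self.n) for k, v in counts.items()}

    def to_frame(self) -> pd.DataFrame:
        """Long-format table: block, category, count, percentage."""
        rows = []
        for block in ("sex", "age", "country", "reporter", "outcomes", "year"):
            for cat, cnt in getattr(self, block).items():
                rows.append((block, cat, cnt, pct(cnt, self.n)))
        return pd.DataFrame(rows, columns=["block", "category", "count", "percentage"])


def _age_bins(age_years: pd.Series) -> pd.Series:
    bins = pd.Series("unknown", index=age_years.index, dtype=object)
    known = age_years.notna()
    bins[known & (age_years < 18)] = "<18"
    bins[known & (age_years >= 18) & (age_years < 65)] = "18-<65"
    bins[known & (age_years >= 65)] = ">=65"
    return bins


def summarize_characteristics(demo: pd.DataFrame, outc: pd.DataFrame,
                              country_field: str = "reporter_country",
                              top_countries: int = 2) -> CohortSummary:
    """Descriptive summary of a (deduplicated, cohort-filtered) DEMO frame.

    Parameters
    ----------
    demo : cohort DEMO frame (one row per report).
    outc : OUTC frame; restricted here to the cohort's primaryids.
    country_field : which DEMO country column feeds the country block
        ("reporter_country" or "occr_country").
    top_countries : number of most-frequent countries listed individually;
        the remainder (including blank entries) pools into "other".
    """
    if demo.empty:
        raise ValidationError("cohort is empty")
    n = len(demo)

    sex = {lab: int((demo["sex"] == lab).sum()) for lab in SEX_LABELS}

    bins = _age_bins(demo["age_years"])
    age = {lab: int((bins == lab).sum()) for lab in AGE_BIN_LABELS}

    country_raw = demo[country_field].replace("", np.nan)
    top = country_raw.value_counts().head(top_countries)
    country = {c: int(k) for c, k in top.items()}
    country["other"] = n - int(top.sum())

    reporter = demo["reporter_type"].value_counts().to_dict()
    reporter = {k: int(v) for k, v in reporter.items()}

    cohort_ids = set(demo["primaryid"])
    oc = outc[outc["primaryid"].isin(cohort_ids)]
    labelled = oc.assign(label=oc["outcome_code"].map(OUTCOME_LABELS)).dropna(subset=["label"])
    per_report = labelled.drop_duplicates(["primaryid", "label"])
    outcomes = {lab: 0 for lab in ("death", "disability", "life-threatening",
                                   "hospitalization", "other")}
    outcomes.update({k: int(v) for k, v in per_report["label"].value_counts().items()})
    outcomes["unknown"] = n - per_report["primaryid"].nunique()

    yr = demo["report_year"]
    year = {str(int(y)): int(c) for y, c in yr.value_counts().sort_index().items()}
    n_missing_year = int(yr.isna().sum())
    if n_missing_year:
        year["unknown"] = n_missing_year

    return CohortSummary(n=n, sex=sex, age=age, country=country,
                         reporter=reporter, outcomes=outcomes, year=year)
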