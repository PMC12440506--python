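"""Time-to-onset from therapy start to adverse-event date.

Onset is the calendar-day difference between the event date (EVENT_DT) and
the start of target-drug therapy (START_DT), computed once per report.  Only
fully specified dates enter the arithmetic; everything else is excluded with
an explicit status rather than silently dropped:

``missing_date``
    either date absent entirely.
``partial_date``
    a date present but truncated to year or year-month precision.
``negative_interval``
    the event predates therapy start — a data-entry error.

Start dates come from the THER table by default (therapy episodes keyed to
the drug sequence number), falling back to the DRUG table's start column; a
report with several target primary-suspect mentions uses its earliest
complete start date (onset relative to first exposure).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Iterable, Optional

import numpy as np
import pandas as pd

ONSET_BINS = (
    ("<=30 d", 0, 30),
    ("31-60 d", 31, 60),
    ("61-90 d", 61, 90),
    ("91-180 d", 91, 180),
    ("181-360 d", 181, 360),
    (">360 d", 361, None),
)

STATUSES = ("missing_date", "partial_date", "negative_interval")


def _date_class(token: pd.Series) -> pd.Series:
    """'complete' / 'partial' / 'missing' per raw date token."""
    tok = token.fillna("").astype(str).str.strip()
    out = pd.Series("missing", index=token.index, dtype=object)
    out[tok.str.len().isin([4, 6])] = "partial"
    out[tok.str.len() == 8] = "complete"
    return out


def _to_datetime(token: pd.Series) -> pd.Series:
    return pd.to_datetime(token.where(token.str.len() == 8), format="%Y%m%d",
                          errors="coerce")


def compute_onset(demo: pd.DataFrame, drug: pd.DataFrame,
                  ther: Optional[pd.DataFrame], target_ids: Iterable[str],
                  names: Iterable[str], role: str = "PS",
                  start_source: str = "ther") -> pd.DataFrame:
    """One onset record per target report.

    Parameters
    ----------
    demo : deduplicated DEMO frame (supplies EVENT_DT).
    drug : DRUG frame (identifies the target mentions and their sequence).
    ther : THER frame with therapy start dates, or None.
    target_ids : primaryids of the cohort.
    names : target drug name strings (generic + brand).
    start_source : "ther" (default; falls back to the DRUG start column for
        reports without a therapy record) or "drug".

    Returns
    -------
    DataFrame with columns ``primaryid``, ``onset_days`` (nullable Int64)
    and ``status`` (empty string when onset_days is present).
    """
    target_ids = set(target_ids)
    names = {str(n).strip().upper() for n in names}
    mentions = drug[(drug["primaryid"].isin(target_ids))
                    & (drug["role_code"] == role)
                    & (drug["drugname"].isin(names)
                       | drug["active_ingredient"].isin(names))]

    # candidate start tokens per mention, by configured source
    starts = mentions[["primaryid", "drug_seq"]].copy()
    if start_source not in ("ther", "drug"):
        raise ValueError(f"unknown start_source: {start_source!r}")
    drug_start = mentions["start_dt"].fillna("").astype(str).values
    if start_source == "ther" and ther is not None and not ther.empty:
        t = ther.rename(columns={"start_dt": "ther_start"})
        starts = starts.merge(t[["primaryid", "drug_seq", "ther_start"]],
                              on=["primaryid", "drug_seq"], how="left")
        ther_start = starts["ther_start"].fillna("").astype(str)
        starts["start_tok"] = ther_start.where(ther_start != "", drug_start)
    else:
        starts["start_tok"] = drug_start

    # earliest complete start date per report; else best available class
    starts["cls"] = _date_class(starts["start_tok"])
    complete = starts[starts["cls"] == "complete"]
    first_start = complete.groupby("primaryid")["start_tok"].min()

    demo_t = demo[demo["primaryid"].isin(target_ids)][["primaryid", "event_dt"]].copy()
    demo_t["event_cls"] = _date_class(demo_t["event_dt"])
    demo_t["start_tok"] = demo_t["primaryid"].map(first_start)
    has_partial_start = set(starts.loc[starts["cls"] == "partial", "primaryid"])
    no_complete = demo_t["start_tok"].isna()
    demo_t["start_cls"] = np.where(~no_complete, "complete",
                                   np.where(demo_t["primaryid"].isin(has_partial_start),
                                            "partial", "missing"))

    ev = _to_datetime(demo_t["event_dt"].fillna("").astype(str))
    st = _to_datetime(demo_t["start_tok"].fillna("").astype(str))
    days = (ev - st).dt.days

    status = np.full(len(demo_t), "", dtype=object)
    missing = (demo_t["event_cls"] == "missing") | (demo_t["start_cls"] == "missing")
    partial = ~missing & ((demo_t["event_cls"] == "partial")
                          | (demo_t["start_cls"] == "partial"))
    negative = ~missing & ~partial & (days < 0)
    status[missing.values] = "missing_date"
    status[partial.values] = "partial_date"
    status[negative.values] = "negative_interval"

    out = pd.DataFrame({
        "primaryid": demo_t["primaryid"].values,
        "onset_days": days.where(status == "").astype("Int64").values,
        "status": status,
    })
    return out.sort_values("primaryid", kind="mergesort").reset_index(drop=True)


@dataclass
class OnsetSummary:
    """Binned time-to-onset distribution over evaluable reports."""

    bins: Dict[str, int]
    evaluable_n: int
    median_days: Optional[int]
    excluded: Dict[str, int]

    def percentages(self) -> Dict[str, float]:
        if self.evaluable_n == 0:
            return {label: float("nan") for label in self.bins}
        return {label: round(100.0 * k / self.evaluable_n, 2)
                for label, k in self.bins.items()}

    def to_frame(self) -> pd.DataFrame:
        pcts = self.percentages()
        return pd.DataFrame({
            "bin": list(self.bins),
            "count": list(self.bins.values()),
            "percentage": [pcts[k] for k in self.bins],
        })


def bin_label(days: int) -> str:
    """The onset bin containing a nonnegative day count."""
    if days < 0:
        raise ValueError("onset days must be nonnegative")
    for label, lo, hi in ONSET_BINS:
        if hi is None or days <= hi:
            return label
    raise AssertionError("unreachable")


def summarize_onset(records: pd.DataFrame) -> OnsetSummary:
    """Bin counts, lower median and exclusion tally for onset records.

    Bins are 30-day multiples up to three months, then 91-180, 181-360 and
    >360 days; the median is the lower median of the evaluable day counts.
    With no evaluable record the bins are zero and the median undefined
    (None).
    """
    evaluable = records[records["status"] == ""]
    days = evaluable["onset_days"].astype(int)
    bins = {label: 0 for label, _, _ in ONSET_BINS}
    for label, lo, hi in ONSET_BINS:
        if hi is None:
            bins[label] = int((days >= lo).sum())
        else:
            bins[label] = int(((days >= lo) & (days <= hi)).sum())
    excluded = {s: int((records["status"] == s).sum()) for s in STATUSES}
    if len(days):
        ordered = np.sort(days.values)
        median = int(ordered[(len(ordered) - 1) // 2])  # lower median
    else:
        median = None
    return OnsetSummary(bins=bins, evaluable_n=int(len(days)),
                        median_days=median, excluded=excluded)
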