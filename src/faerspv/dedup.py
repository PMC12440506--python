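"""FDA-style deduplication of spontaneous case reports.

A FAERS case accumulates versions over time: every version of the same case
shares a CASEID but carries its own PRIMARYID.  Counting each version as a
separate report inflates every downstream statistic, so the database is
collapsed to one row per case using the FDA-recommended rule: within a
CASEID group keep the version with the latest FDA receipt date (FDA_DT),
breaking ties by the numerically larger PRIMARYID.  An absent FDA_DT sorts
earliest, so versions with a known receipt date win.
"""

from __future__ import annotations

from typing import Tuple

import pandas as pd


def _fda_sort_key(fda_dt: pd.Series) -> pd.Series:
    """Zero-padded 8-char key; partial tokens pad with '00', absent -> all zeros."""
    key = fda_dt.fillna("").astype(str).str.strip()
    return key.str.pad(8, side="right", fillchar="0")


def _primaryid_numeric(primaryid: pd.Series) -> pd.Series:
    num = pd.to_numeric(primaryid, errors="coerce")
    # non-numeric identifiers lose every tie but are never dropped outright
    return num.fillna(-1)


def deduplicate(demo: pd.DataFrame) -> Tuple[pd.DataFrame, int]:
    """Collapse report versions to one row per case.

    Parameters
    ----------
    demo : DataFrame
        Normalized DEMO frame (``faerspv.io.read_table``); must contain
        ``primaryid``, ``caseid`` and ``fda_dt`` columns.

    Returns
    -------
    (kept, dropped_count)
        *kept* has exactly one row per distinct caseid, sorted by caseid;
        ``len(kept) + dropped_count == len(demo)``.
    """
    if demo.empty:
        return demo.copy(), 0
    work = demo.assign(
        _fda_key=_fda_sort_key(demo["fda_dt"]),
        _pid_num=_primaryid_numeric(demo["primaryid"]),
    )
    # identical (primaryid, caseid) rows are byte-duplicates, keep one
    work = work.drop_duplicates(subset=["caseid", "primaryid"])
    work = work.sort_values(["caseid", "_fda_key", "_pid_num"],
                            kind="mergesort")
    kept = (work.groupby("caseid", sort=True).tail(1)
                .drop(columns=["_fda_key", "_pid_num"])
                .sort_values("caseid", kind="mergesort")
                .reset_index(drop=True))
    return kept, len(demo) - len(kept)


def filter_to_reports(frame: pd.DataFrame, kept_ids) -> pd.DataFrame:
    """Restrict a DRUG/REAC/OUTC/THER frame to the kept report versions."""
    keep = frame["primaryid"].isin(set(kept_ids))
    return frame[keep].reset_index(drop=True)
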