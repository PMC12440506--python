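"""Disproportionality statistics and the joint positive-signal criterion.

Four estimators of reporting disproportionality are computed for every 2x2
table, each with its conventional interval bound:

ROR (reporting odds ratio)
    ``ad / bc`` with a log-normal 95% CI,
    ``exp(ln ROR +/- 1.96 s)``, ``s = sqrt(1/a + 1/b + 1/c + 1/d)``.
PRR (proportional reporting ratio)
    ``[a/(a+b)] / [c/(c+d)]`` paired with the (uncorrected) Pearson
    chi-squared statistic ``n (ad - bc)^2 / [(a+b)(c+d)(a+c)(b+d)]``.
IC (information component, BCPNN family)
    ``log2[ a n / ((a+b)(a+c)) ]`` — the base-2 log of the observed-to-
    expected reporting ratio — with lower credibility bound
    ``IC025 = IC - 2 s / ln 2``.
EBGM (empirical Bayes geometric mean, MGPS family)
    the same observed-to-expected ratio on the natural scale,
    ``a n / ((a+b)(a+c))``, with 5th-percentile bound
    ``EBGM05 = exp(ln EBGM - 1.64 s)``.

These are the closed-form variants of the two Bayesian methods: the point
estimate is the relative report rate (so ``IC = log2(EBGM)`` holds exactly)
and the bounds are normal-approximation quantiles on the log scale, not the
output of a full hyperprior fit.  They behave like the shrinkage estimators
at the large counts where signal criteria bite, and keep every statistic an
auditable closed form.

A term is a *joint* positive signal only when all four per-algorithm
criteria hold simultaneously (``SignalCriteria`` for the defaults); this
AND-combination trades sensitivity for a lower false-positive rate.

The module-level functions operate on a single :class:`ContingencyTable`;
:class:`Disproportionality` / :class:`DisproportionalityResults` expose the
same computation over a whole term set in the model / fitted-results idiom.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Dict, Iterable, Mapping, Optional, Set, Tuple

import numpy as np
import pandas as pd

from .contingency import ContingencyTable, build_pt_tables, build_soc_tables
from .io import PtSocMap

_Z95 = 1.96      # two-sided 95% normal quantile (ROR CI)
_Z90 = 1.64      # one-sided 5th percentile (EBGM05)
_IC_MULT = 2.0   # IC025 = IC - 2 s / ln 2


@dataclass(frozen=True)
class SignalCriteria:
    """Per-algorithm positive-signal thresholds (conventional defaults).

    ROR: ``a >= ror_min_a`` and CI lower bound ``> ror_lo_gt``.
    PRR: ``a >= prr_min_a``, ``PRR >= prr_min`` and ``chi2 >= chi2_min``.
    BCPNN: ``IC025 > ic025_gt``.  MGPS: ``EBGM05 > ebgm05_gt``.
    """

    ror_min_a: int = 3
    ror_lo_gt: float = 1.0
    prr_min_a: int = 3
    prr_min: float = 2.0
    chi2_min: float = 4.0
    ic025_gt: float = 0.0
    ebgm05_gt: float = 2.0

    def validate(self) -> None:
        for name, value in self.__dict__.items():
            if not math.isfinite(value):
                raise ValueError(f"criterion {name} must be finite")


def _cells(t) -> Tuple[float, float, float, float]:
    return float(t.a), float(t.b), float(t.c), float(t.d)


def _log_se(a: float, b: float, c: float, d: float) -> float:
    if min(a, b, c, d) <= 0:
        return math.nan
    return math.sqrt(1 / a + 1 / b + 1 / c + 1 / d)


def ror(t: ContingencyTable) -> Tuple[float, float, float]:
    """Reporting odds ratio with 95% CI; NaN triple when any cell is zero."""
    a, b, c, d = _cells(t)
    if a <= 0 or b <= 0 or c <= 0 or d <= 0:
        return (math.nan, math.nan, math.nan)
    point = (a * d) / (b * c)
    s = _log_se(a, b, c, d)
    return (point, point * math.exp(-_Z95 * s), point * math.exp(_Z95 * s))


def prr(t: ContingencyTable) -> Tuple[float, float]:
    """Proportional reporting ratio and uncorrected chi-squared statistic."""
    a, b, c, d = _cells(t)
    n = a + b + c + d
    if a <= 0 or c <= 0 or (a + b) <= 0 or (c + d) <= 0:
        return (math.nan, math.nan)
    point = (a / (a + b)) / (c / (c + d))
    denom = (a + b) * (c + d) * (a + c) * (b + d)
    chi2 = n * (a * d - b * c) ** 2 / denom if denom > 0 else math.nan
    return (point, chi2)


def relative_report_rate(t: ContingencyTable) -> float:
    """Observed-to-expected reporting ratio a*n / ((a+b)(a+c))."""
    a, b, c, d = _cells(t)
    if a <= 0:
        return math.nan
    return a * (a + b + c + d) / ((a + b) * (a + c))


def bcpnn_ic(t: ContingencyTable) -> Tuple[float, float]:
    """Information component (bits) and its lower bound IC025."""
    rrr = relative_report_rate(t)
    if math.isnan(rrr):
        return (math.nan, math.nan)
    ic = math.log2(rrr)
    s = _log_se(*_cells(t))
    return (ic, ic - _IC_MULT * s / math.log(2))


def mgps_ebgm(t: ContingencyTable) -> Tuple[float, float]:
    """Empirical Bayes geometric mean and its 5th-percentile bound EBGM05."""
    ebgm = relative_report_rate(t)
    if math.isnan(ebgm):
        return (math.nan, math.nan)
    s = _log_se(*_cells(t))
    return (ebgm, ebgm * math.exp(-_Z90 * s))


def _stats_frame(terms, a, b, c, d) -> pd.DataFrame:
    """Vectorized version of the four estimators over parallel count arrays."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    c = np.asarray(c, dtype=float)
    d = np.asarray(d, dtype=float)
    n = a + b + c + d
    with np.errstate(divide="ignore", invalid="ignore"):
        all_pos = (a > 0) & (b > 0) & (c > 0) & (d > 0)
        s = np.where(all_pos, np.sqrt(1 / a + 1 / b + 1 / c + 1 / d), np.nan)

        ror_v = np.where(all_pos, (a * d) / (b * c), np.nan)
        ror_lo = ror_v * np.exp(-_Z95 * s)
        ror_hi = ror_v * np.exp(_Z95 * s)

        prr_ok = (a > 0) & (c > 0) & (a + b > 0) & (c + d > 0)
        prr_v = np.where(prr_ok, (a / (a + b)) / (c / (c + d)), np.nan)
        denom = (a + b) * (c + d) * (a + c) * (b + d)
        chi2 = np.where(prr_ok & (denom > 0),
                        n * (a * d - b * c) ** 2 / denom, np.nan)

        rrr = np.where(a > 0, a * n / ((a + b) * (a + c)), np.nan)
        ic = np.log2(rrr)
        ic025 = ic - _IC_MULT * s / np.log(2)
        ebgm05 = rrr * np.exp(-_Z90 * s)

    return pd.DataFrame({
        "term": list(terms),
        "a": a.astype(int), "b": b.astype(int),
        "c": c.astype(int), "d": d.astype(int),
        "ror": ror_v, "ror_lo": ror_lo, "ror_hi": ror_hi,
        "prr": prr_v, "chi2": chi2,
        "ebgm": rrr, "ebgm05": ebgm05,
        "ic": ic, "ic025": ic025,
    })


def _apply_flags(frame: pd.DataFrame, criteria: SignalCriteria) -> pd.DataFrame:
    out = frame.copy()
    a = out["a"]
    # NaN comparisons are False, so undefined statistics never flag
    out["ror_flag"] = (a >= criteria.ror_min_a) & (out["ror_lo"] > criteria.ror_lo_gt)
    out["prr_flag"] = ((a >= criteria.prr_min_a)
                       & (out["prr"] >= criteria.prr_min)
                       & (out["chi2"] >= criteria.chi2_min))
    out["ic_flag"] = out["ic025"] > criteria.ic025_gt
    out["ebgm_flag"] = out["ebgm05"] > criteria.ebgm05_gt
    out["joint_flag"] = (out["ror_flag"] & out["prr_flag"]
                         & out["ic_flag"] & out["ebgm_flag"])
    return out


def evaluate_signals(tables: Mapping[str, ContingencyTable],
                     criteria: Optional[SignalCriteria] = None,
                     continuity: bool = False) -> pd.DataFrame:
    """All four statistics, bounds and flags for every term.

    Parameters
    ----------
    tables : term -> ContingencyTable
    criteria : thresholds; conventional defaults when omitted.
    continuity : apply a Haldane +0.5 correction to every cell before
        computing statistics (rescues zero-cell tables; off by default —
        undefined statistics are reported as NaN instead).

    Returns one row per term, sorted by descending case count ``a``.
    """
    criteria = criteria or SignalCriteria()
    criteria.validate()
    terms = list(tables)
    cells = [tables[t].continuity_corrected() if continuity else tables[t]
             for t in terms]
    frame = _stats_frame(terms,
                         [t.a for t in cells], [t.b for t in cells],
                         [t.c for t in cells], [t.d for t in cells])
    if continuity:
        # flags still gate on the raw case count
        frame["a"] = [tables[t].a for t in terms]
        frame[["b", "c", "d"]] = [[tables[t].b, tables[t].c, tables[t].d]
                                  for t in terms]
    frame = _apply_flags(frame, criteria)
    return (frame.sort_values(["a", "term"], ascending=[False, True],
                              kind="mergesort")
                 .reset_index(drop=True))


class Disproportionality:
    """Disproportionality model for one target drug against the database.

    Built either from prebuilt 2x2 tables or directly from the event pairs
    and the target cohort (``from_events``).  ``fit`` evaluates the four
    estimators and the joint criterion, returning a
    :class:`DisproportionalityResults`.

    Examples
    --------
    >>> model = Disproportionality.from_events(reac, target_ids)   # doctest: +SKIP
    >>> res = model.fit()                                          # doctest: +SKIP
    >>> res.signals                                                # doctest: +SKIP
    """

    def __init__(self, tables: Mapping[str, ContingencyTable],
                 level: str = "pt", unmapped_pts: Optional[Set[str]] = None):
        self.tables: Dict[str, ContingencyTable] = dict(tables)
        self.level = level
        self.unmapped_pts: Set[str] = set(unmapped_pts or ())

    @classmethod
    def from_events(cls, events: pd.DataFrame, target_ids: Iterable[str],
                    level: str = "pt", pt_soc_map: Optional[PtSocMap] = None,
                    unit: str = "pair") -> "Disproportionality":
        """Build the model from REAC pairs and the target-cohort primaryids.

        ``level="soc"`` collapses PTs through *pt_soc_map* first; PTs absent
        from the vocabulary are recorded on ``unmapped_pts``.
        """
        if level == "pt":
            return cls(build_pt_tables(events, target_ids, unit=unit), level="pt")
        if level == "soc":
            if pt_soc_map is None:
                raise ValueError("SOC-level analysis requires a PT->SOC map")
            tables, unmapped = build_soc_tables(events, target_ids,
                                                pt_soc_map, unit=unit)
            return cls(tables, level="soc", unmapped_pts=unmapped)
        raise ValueError(f"unknown level: {level!r}")

    def fit(self, criteria: Optional[SignalCriteria] = None,
            continuity: bool = False) -> "DisproportionalityResults":
        frame = evaluate_signals(self.tables, criteria, continuity=continuity)
        return DisproportionalityResults(frame, level=self.level,
                                         criteria=criteria or SignalCriteria(),
                                         unmapped_pts=self.unmapped_pts)


class DisproportionalityResults:
    """Fitted disproportionality estimates for every term.

    Attributes
    ----------
    frame : DataFrame
        Full-precision statistics, bounds and flags, one row per term,
        sorted by descending case count.
    signals : DataFrame
        The jointly positive subset of ``frame``.
    """

    def __init__(self, frame: pd.DataFrame, level: str,
                 criteria: SignalCriteria, unmapped_pts: Set[str]):
        self.frame = frame
        self.level = level
        self.criteria = criteria
        self.unmapped_pts = unmapped_pts

    @property
    def signals(self) -> pd.DataFrame:
        return self.frame[self.frame["joint_flag"]].reset_index(drop=True)

    def summary(self, min_count: int = 0) -> pd.DataFrame:
        """Display table in the conventional published layout.

        Columns: term, case count, ``ROR (95% CI)``, ``PRR (chi2)``,
        ``EBGM (EBGM05)``, ``IC (IC025)`` and the joint-signal flag, with
        statistics rounded to 2 decimals.  ``min_count`` drops rare terms
        from the display only.
        """
        def fmt(x: float) -> str:
            return "NA" if pd.isna(x) else f"{x:.2f}"

        rows = self.frame[self.frame["a"] >= min_count]
        label = "SOC" if self.level == "soc" else "PT"
        return pd.DataFrame({
            label: rows["term"],
            "Case reports": rows["a"],
            "ROR (95% CI)": [f"{fmt(r)} ({fmt(lo)}-{fmt(hi)})" for r, lo, hi in
                             zip(rows["ror"], rows["ror_lo"], rows["ror_hi"])],
            "PRR (chi2)": [f"{fmt(p)} ({fmt(x)})" for p, x in
                           zip(rows["prr"], rows["chi2"])],
            "EBGM (EBGM05)": [f"{fmt(e)} ({fmt(lo)})" for e, lo in
                              zip(rows["ebgm"], rows["ebgm05"])],
            "IC (IC025)": [f"{fmt(i)} ({fmt(lo)})" for i, lo in
                           zip(rows["ic"], rows["ic025"])],
            "joint_signal": rows["joint_flag"],
        }).reset_index(drop=True)

    def __repr__(self) -> str:
        return (f"<DisproportionalityResults level={self.level} "
                f"terms={len(self.frame)} signals={int(self.frame['joint_flag'].sum())}>")
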