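"""Reading and writing FAERS-dialect quarterly tables.

The FAERS Quarterly Data Extract ships ``$``-delimited ASCII tables with a
header row and no quoting.  This module loads the five tables the analysis
needs (DEMO, DRUG, REAC, OUTC, THER) into pandas DataFrames with normalized
columns, plus the user-supplied PT -> SOC vocabulary mapping (the licensed
MedDRA dictionary cannot be redistributed, so the hierarchy arrives as a
plain two-column file).

Normalized schemas
------------------
DEMO : primaryid, caseid, fda_dt, event_dt, sex, age_years,
       reporter_country, occr_country, reporter_type, report_year
DRUG : primaryid, drug_seq, role_code, drugname, active_ingredient, start_dt
REAC : primaryid, pt            (unique per report)
OUTC : primaryid, outcome_code
THER : primaryid, drug_seq, start_dt

Date columns hold the raw 4/6/8-digit tokens (empty string when absent);
:mod:`faerspv.dates` parses them on demand.  Free-text drug and PT strings
are trimmed and uppercased, since FAERS capitalization is inconsistent.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Dict, Iterable, Mapping, Optional, Set

import pandas as pd

logger = logging.getLogger(__name__)

DELIMITER = "$"

TABLE_KINDS = ("DEMO", "DRUG", "REAC", "OUTC", "THER")

#: columns each table kind must provide (lowercased header names)
REQUIRED_COLUMNS: Dict[str, tuple] = {
    "DEMO": ("primaryid", "caseid", "fda_dt", "event_dt", "sex", "age",
             "age_cod", "occp_cod", "reporter_country"),
    "DRUG": ("primaryid", "drug_seq", "role_cod", "drugname"),
    "REAC": ("primaryid", "pt"),
    "OUTC": ("primaryid", "outc_cod"),
    "THER": ("primaryid", "dsg_drug_seq", "start_dt"),
}

SEX_CODES = {"F": "female", "M": "male", "UNK": "unknown"}

#: FAERS occp_cod -> reporter category as reported in descriptive tables
REPORTER_CODES = {
    "MD": "physician",
    "PH": "pharmacist",
    "OT": "other health professional",
    "HP": "other health professional",
    "CN": "consumer",
    "LW": "lawyer",
}

ROLE_CODES = ("PS", "SS", "C", "I")

OUTCOME_CODES = ("DE", "DS", "LT", "HO", "OT", "RI", "CA")

#: age-unit code -> factor converting the reported value to years
AGE_UNIT_TO_YEARS = {
    "DEC": 10.0,
    "YR": 1.0,
    "MON": 1.0 / 12.0,
    "WK": 1.0 / 52.0,
    "DY": 1.0 / 365.25,
}


class SchemaError(ValueError):
    """A required column is missing or a file violates the dialect."""


class ValidationError(ValueError):
    """Input data violates a contract (duplicates, empty sets, ...)."""


class MissingPtError(KeyError):
    """A preferred term has no SOC in the supplied vocabulary mapping."""


@dataclass(frozen=True)
class PtSocMap:
    """Total mapping from preferred term to its primary System Organ Class."""

    entries: Mapping[str, str]

    def __len__(self) -> int:
        return len(self.entries)

    def __contains__(self, pt: str) -> bool:
        return pt.strip().upper() in self.entries

    def soc_of(self, pt: str) -> str:
        key = pt.strip().upper()
        try:
            return self.entries[key]
        except KeyError:
            raise MissingPtError(pt) from None

    def get(self, pt: str, default: Optional[str] = None) -> Optional[str]:
        return self.entries.get(pt.strip().upper(), default)

    def unmapped(self, pts: Iterable[str]) -> Set[str]:
        """The subset of *pts* absent from the vocabulary."""
        return {p for p in pts if p.strip().upper() not in self.entries}


def _clean_date_column(series: pd.Series, column: str, path: object) -> pd.Series:
    """Validate date tokens; malformed tokens become absent with a warning."""
    from .dates import parse_date_token

    raw = series.fillna("").astype(str).str.strip()
    # strip a trailing ".0" left by numeric inference on an all-digit column
    raw = raw.str.replace(r"\.0$", "", regex=True)
    cleaned = {}
    n_bad = 0
    for token in raw.unique():
        try:
            parse_date_token(token)
            cleaned[token] = token
        except ValueError:
            cleaned[token] = ""
            n_bad += int((raw == token).sum())
    if n_bad:
        logger.warning("%s: %d malformed %s token(s) treated as absent",
                       path, n_bad, column)
    return raw.map(cleaned)


def _text(series: pd.Series, upper: bool = False) -> pd.Series:
    out = series.fillna("").astype(str).str.strip()
    return out.str.upper() if upper else out


def _read_raw(path, table_kind: str) -> pd.DataFrame:
    if table_kind not in TABLE_KINDS:
        raise ValueError(f"unknown table kind: {table_kind!r}")
    try:
        frame = pd.read_csv(path, sep=DELIMITER, dtype=str,
                            keep_default_na=False, na_values=[""],
                            skip_blank_lines=True, engine="c", quoting=3)
    except OSError as exc:
        raise OSError(f"cannot read {table_kind} table at {path}: {exc}") from exc
    frame.columns = [c.strip().lower() for c in frame.columns]
    missing = [c for c in REQUIRED_COLUMNS[table_kind] if c not in frame.columns]
    if missing:
        raise SchemaError(
            f"{path}: {table_kind} header is missing required column(s): "
            + ", ".join(missing))
    return frame


def _normalize_age_years(age: pd.Series, age_cod: pd.Series) -> pd.Series:
    value = pd.to_numeric(age, errors="coerce")
    factor = _text(age_cod, upper=True).map(AGE_UNIT_TO_YEARS)
    years = value * factor
    return years.where(years >= 0)


def read_table(path, table_kind: str) -> pd.DataFrame:
    """Read one FAERS quarterly table into its normalized DataFrame.

    Parameters
    ----------
    path : path-like
        ``$``-delimited ASCII file with a header row.
    table_kind : {"DEMO", "DRUG", "REAC", "OUTC", "THER"}

    Returns
    -------
    DataFrame with the normalized schema for that kind (module docstring).
    Unknown extra columns are ignored; missing optional fields become empty
    strings / NaN; malformed date tokens are kept as absent dates with a
    logged warning.
    """
    raw = _read_raw(path, table_kind)
    kind = table_kind.upper()

    if kind == "DEMO":
        out = pd.DataFrame({
            "primaryid": _text(raw["primaryid"]),
            "caseid": _text(raw["caseid"]),
            "fda_dt": _clean_date_column(raw["fda_dt"], "fda_dt", path),
            "event_dt": _clean_date_column(raw["event_dt"], "event_dt", path),
            "sex": _text(raw["sex"], upper=True).map(SEX_CODES).fillna("unknown"),
            "age_years": _normalize_age_years(raw["age"], raw["age_cod"]),
            "reporter_country": _text(raw["reporter_country"]),
            "occr_country": _text(raw["occr_country"]) if "occr_country" in raw
                             else pd.Series("", index=raw.index),
            "reporter_type": _text(raw["occp_cod"], upper=True)
                             .map(REPORTER_CODES).fillna("unknown"),
        })
        year = out["fda_dt"].str.slice(0, 4)
        out["report_year"] = pd.to_numeric(year.where(year != ""), errors="coerce").astype("Int64")
        return out

    if kind == "DRUG":
        role = _text(raw["role_cod"], upper=True)
        bad_roles = ~role.isin(ROLE_CODES) & (role != "")
        if bad_roles.any():
            logger.warning("%s: %d unknown role code(s) kept verbatim",
                           path, int(bad_roles.sum()))
        start = (_clean_date_column(raw["start_dt"], "start_dt", path)
                 if "start_dt" in raw else pd.Series("", index=raw.index))
        return pd.DataFrame({
            "primaryid": _text(raw["primaryid"]),
            "drug_seq": pd.to_numeric(raw["drug_seq"], errors="coerce").astype("Int64"),
            "role_code": role,
            "drugname": _text(raw["drugname"], upper=True),
            "active_ingredient": (_text(raw["prod_ai"], upper=True)
                                  if "prod_ai" in raw
                                  else pd.Series("", index=raw.index)),
            "start_dt": start,
        })

    if kind == "REAC":
        out = pd.DataFrame({
            "primaryid": _text(raw["primaryid"]),
            "pt": _text(raw["pt"], upper=True),
        })
        out = out[out["pt"] != ""]
        # duplicate (report, PT) mentions collapse to one
        return out.drop_duplicates(ignore_index=True)

    if kind == "OUTC":
        code = _text(raw["outc_cod"], upper=True)
        bad = ~code.isin(OUTCOME_CODES) & (code != "")
        if bad.any():
            logger.warning("%s: %d unknown outcome code(s) dropped", path, int(bad.sum()))
        out = pd.DataFrame({"primaryid": _text(raw["primaryid"]),
                            "outcome_code": code})
        return out[out["outcome_code"].isin(OUTCOME_CODES)].reset_index(drop=True)

    # THER
    return pd.DataFrame({
        "primaryid": _text(raw["primaryid"]),
        "drug_seq": pd.to_numeric(raw["dsg_drug_seq"], errors="coerce").astype("Int64"),
        "start_dt": _clean_date_column(raw["start_dt"], "start_dt", path),
    })


_SEX_TO_CODE = {v: k for k, v in SEX_CODES.items()}
_REPORTER_TO_CODE = {"physician": "MD", "pharmacist": "PH",
                     "other health professional": "OT", "consumer": "CN",
                     "lawyer": "LW", "unknown": ""}


def write_table(frame: pd.DataFrame, path, table_kind: str) -> None:
    """Write a normalized DataFrame back out in the FAERS ``$`` dialect.

    Inverts the normalization (codes for labels, age in years) so that
    re-reading the file reproduces the normalized record set field for field.
    """
    kind = table_kind.upper()
    if kind == "DEMO":
        out = pd.DataFrame({
            "primaryid": frame["primaryid"],
            "caseid": frame["caseid"],
            "fda_dt": frame["fda_dt"],
            "event_dt": frame["event_dt"],
            "sex": frame["sex"].map(_SEX_TO_CODE).fillna("UNK"),
            "age": frame["age_years"],
            "age_cod": frame["age_years"].notna().map({True: "YR", False: ""}),
            "occp_cod": frame["reporter_type"].map(_REPORTER_TO_CODE).fillna(""),
            "reporter_country": frame["reporter_country"],
            "occr_country": frame["occr_country"],
        })
    else:
        renames = {
            "DRUG": {"role_code": "role_cod", "active_ingredient": "prod_ai"},
            "REAC": {},
            "OUTC": {"outcome_code": "outc_cod"},
            "THER": {"drug_seq": "dsg_drug_seq"},
        }[kind]
        out = frame.rename(columns=renames)
    out.to_csv(path, sep=DELIMITER, index=False)


def read_pt_soc_map(path, sep: Optional[str] = None) -> PtSocMap:
    """Read the two-column (pt, soc) vocabulary mapping.

    The delimiter is sniffed unless given.  Duplicate PT rows pointing at
    different SOCs are a validation error (each PT has exactly one primary
    SOC); byte-identical duplicate rows collapse silently.
    """
    frame = pd.read_csv(path, sep=sep, engine="python" if sep is None else "c",
                        dtype=str, keep_default_na=False)
    if frame.shape[1] < 2:
        raise SchemaError(f"{path}: PT->SOC mapping needs two columns (pt, soc)")
    pts = _text(frame.iloc[:, 0], upper=True)
    socs = _text(frame.iloc[:, 1])
    pairs = pd.DataFrame({"pt": pts, "soc": socs}).drop_duplicates()
    pairs = pairs[pairs["pt"] != ""]
    conflicts = pairs["pt"][pairs["pt"].duplicated()].unique()
    if len(conflicts):
        raise ValidationError(
            "PT(s) mapped to more than one SOC: " + ", ".join(sorted(conflicts)))
    return PtSocMap(entries=dict(zip(pairs["pt"], pairs["soc"])))


def write_pt_soc_map(mapping: PtSocMap, path, sep: str = "\t") -> None:
    frame = pd.DataFrame(sorted(mapping.entries.items()), columns=["pt", "soc"])
    frame.to_csv(path, sep=sep, index=False)


def write_results_table(rows: pd.DataFrame, path, sep: str = "\t",
                        decimals: int = 2) -> None:
    """Write a results table as delimited text.

    Float statistics are rounded to *decimals* for display; callers keep the
    full-precision frame in memory.  An empty frame yields a header-only file.
    """
    out = rows.copy()
    for col in out.columns:
        if pd.api.types.is_float_dtype(out[col]):
            out[col] = out[col].round(decimals)
    try:
        out.to_csv(path, sep=sep, index=False)
    except OSError as exc:
        raise OSError(f"cannot write results table to {path}: {exc}") from exc
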