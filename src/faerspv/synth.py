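"""Synthetic spontaneous-report generator with known ground truth.

Emits FAERS-dialect quarterly tables (DEMO/DRUG/REAC/OUTC/THER), a PT -> SOC
mapping file and a plain-text manifest of the truths injected, so every
pipeline stage — ingestion, deduplication, cohort selection, the four
disproportionality statistics and time-to-onset — can be exercised and
scored without touching the real multi-gigabyte archive.

Generative model
----------------
Each case gets exactly one primary-suspect (PS) drug: the target drug with
probability ``target_prevalence`` (its mention randomly uses the generic or
the brand name), otherwise a uniformly drawn background drug.  Additional
drug mentions (secondary suspect / concomitant / interacting) are Poisson
noise.  Given the PS drug, each preferred term is reported independently
with probability ``p_pt``, multiplied by the injected relative risk for
(drug, PT) pairs listed in ``injected_signals`` and capped at 1.  That
independence makes the expected 2x2 table a closed form
(:func:`expected_table`), the recovery oracle for the whole pipeline.

Duplicate case versions share a CASEID with an incremented PRIMARYID and a
strictly later FDA receipt date, so the deduplication rule has an exact
answer recorded in the manifest.  Event dates sit an exponential onset time
after therapy start, with configurable fractions of negative intervals
(data-entry errors), partial tokens and missing dates.

All randomness flows from the single ``seed``; the same config yields
byte-identical files.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Mapping, Tuple

import numpy as np
import pandas as pd

from .io import DELIMITER, ValidationError, write_pt_soc_map, PtSocMap

_EPOCH = np.datetime64("1970-01-01")


def default_pt_vocabulary(n_pts: int = 50, n_socs: int = 8
                          ) -> Tuple[Tuple[str, ...], Dict[str, str]]:
    """Synthetic PT names and their round-robin SOC assignment."""
    pts = tuple(f"PT_{i + 1:03d}" for i in range(n_pts))
    socs = {pt: f"SOC_{(i % n_socs) + 1:02d}" for i, pt in enumerate(pts)}
    return pts, socs


def default_pt_probs(n_pts: int = 50, lo: float = 0.002, hi: float = 0.03
                     ) -> Tuple[float, ...]:
    """Log-spaced background report probabilities per PT."""
    return tuple(float(p) for p in np.geomspace(lo, hi, n_pts))


@dataclass
class SyntheticConfig:
    """Full parameterization of the report generator.

    The defaults emulate a scaled-down spontaneous-report database around a
    rare target drug: the target is primary suspect in 2% of cases, one
    drug-event association is injected at relative risk 5 on a PT with
    ~1% background reporting probability, 10% of cases arrive in multiple
    versions, and dates carry realistic fractions of missing, partial and
    reversed entries.
    """

    n_reports: int = 20_000
    seed: int = 0

    target_generic: str = "OZANIMOD"
    target_brand: str = "ZEPOSIA"
    target_prevalence: float = 0.02
    background_drugs: Tuple[str, ...] = tuple(f"DRUG_{i + 1:02d}" for i in range(20))

    pt_names: Tuple[str, ...] = field(default_factory=lambda: default_pt_vocabulary()[0])
    pt_soc: Dict[str, str] = field(default_factory=lambda: default_pt_vocabulary()[1])
    pt_probs: Tuple[float, ...] = field(default_factory=default_pt_probs)
    #: (drug, pt, relative risk) associations injected into exposed cases
    injected_signals: Tuple[Tuple[str, str, float], ...] = (("OZANIMOD", "PT_030", 5.0),)

    concomitant_mean: float = 1.0
    extra_role_probs: Dict[str, float] = field(
        default_factory=lambda: {"SS": 0.10, "C": 0.85, "I": 0.05})

    duplicate_rate: float = 0.10
    max_extra_versions: int = 2

    sex_probs: Dict[str, float] = field(
        default_factory=lambda: {"F": 0.68, "M": 0.27, "UNK": 0.05})
    age_mean: float = 46.0
    age_sd: float = 16.0
    age_missing_rate: float = 0.24
    age_decade_unit_rate: float = 0.05
    country_probs: Dict[str, float] = field(
        default_factory=lambda: {"US": 0.92, "DE": 0.03, "FR": 0.02,
                                 "GB": 0.02, "JP": 0.01})
    reporter_probs: Dict[str, float] = field(
        default_factory=lambda: {"MD": 0.14, "CN": 0.35, "PH": 0.02,
                                 "OT": 0.48, "LW": 0.005, "": 0.005})
    outcome_rate: float = 0.28
    outcome_probs: Dict[str, float] = field(
        default_factory=lambda: {"HO": 0.35, "OT": 0.45, "DE": 0.05,
                                 "LT": 0.05, "DS": 0.10})

    date_start: str = "2020-01-01"
    date_end: str = "2023-06-30"
    onset_scale_days: float = 120.0
    negative_interval_rate: float = 0.02
    partial_event_date_rate: float = 0.05
    missing_event_date_rate: float = 0.20
    missing_start_date_rate: float = 0.10
    max_reporting_lag_days: int = 60

    # ------------------------------------------------------------------
    def validate(self) -> None:
        if self.n_reports <= 0:
            raise ValidationError("n_reports must be positive")
        if not 0 < self.target_prevalence < 1:
            raise ValidationError("target_prevalence must be in (0, 1)")
        if len(self.pt_names) != len(self.pt_probs):
            raise ValidationError("pt_probs must align with pt_names")
        if any(not 0 <= p <= 1 for p in self.pt_probs):
            raise ValidationError("pt_probs must lie in [0, 1]")
        missing_soc = [pt for pt in self.pt_names if pt not in self.pt_soc]
        if missing_soc:
            raise ValidationError(f"PTs without SOC: {missing_soc[:5]}")
        drugs = set(self.all_drugs())
        for d, pt, rr in self.injected_signals:
            if d not in drugs:
                raise ValidationError(f"injected signal names unknown drug {d!r}")
            if pt not in self.pt_names:
                raise ValidationError(f"injected signal names unknown PT {pt!r}")
            if rr <= 0:
                raise ValidationError("relative risk must be positive")
        for name, mix in (("sex_probs", self.sex_probs),
                          ("country_probs", self.country_probs),
                          ("reporter_probs", self.reporter_probs),
                          ("outcome_probs", self.outcome_probs),
                          ("extra_role_probs", self.extra_role_probs)):
            vals = list(mix.values())
            if any(not 0 <= v <= 1 for v in vals) or abs(sum(vals) - 1) > 1e-9:
                raise ValidationError(f"{name} must be a probability mixture summing to 1")
        for name in ("duplicate_rate", "negative_interval_rate",
                     "partial_event_date_rate", "missing_event_date_rate",
                     "missing_start_date_rate", "age_missing_rate",
                     "age_decade_unit_rate", "outcome_rate"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValidationError(f"{name} must lie in [0, 1]")
        if np.datetime64(self.date_start) >= np.datetime64(self.date_end):
            raise ValidationError("date_start must precede date_end")

    def all_drugs(self) -> Tuple[str, ...]:
        return (self.target_generic,) + tuple(self.background_drugs)

    def target_names(self) -> Tuple[str, str]:
        return (self.target_generic, self.target_brand)

    @classmethod
    def from_mapping(cls, data: Mapping) -> "SyntheticConfig":
        """Build from a (nested) mapping, e.g. a parsed YAML section."""
        kwargs = dict(data)
        if "injected_signals" in kwargs:
            kwargs["injected_signals"] = tuple(
                (str(d), str(p), float(r)) for d, p, r in kwargs["injected_signals"])
        for key in ("background_drugs", "pt_names", "pt_probs"):
            if key in kwargs:
                kwargs[key] = tuple(kwargs[key])
        cfg = cls(**kwargs)
        cfg.validate()
        return cfg


@dataclass(frozen=True)
class ExpectedCounts:
    """Analytic expectation of a 2x2 table (real-valued cells)."""

    a: float
    b: float
    c: float
    d: float

    @property
    def n(self) -> float:
        return self.a + self.b + self.c + self.d

    @property
    def ror(self) -> float:
        return (self.a * self.d) / (self.b * self.c)

    @property
    def ebgm(self) -> float:
        return self.a * self.n / ((self.a + self.b) * (self.a + self.c))


def _rr_lookup(config: SyntheticConfig) -> Dict[Tuple[str, str], float]:
    return {(d, pt): rr for d, pt, rr in config.injected_signals}


def _event_prob(config: SyntheticConfig, ps_drug: str, pt: str) -> float:
    p = config.pt_probs[config.pt_names.index(pt)]
    rr = _rr_lookup(config).get((ps_drug, pt), 1.0)
    return min(1.0, rr * p)


def expected_table(config: SyntheticConfig, drug: str, pt: str) -> ExpectedCounts:
    """Expected (a, b, c, d) for a drug-event pair under the generator.

    Counts are unique report-event pairs among the deduplicated cases, the
    same unit the contingency builder uses, so a large-sample run should
    reproduce these values up to sampling noise.
    """
    config.validate()
    if drug not in config.all_drugs():
        raise ValidationError(f"unknown drug: {drug!r}")
    if pt not in config.pt_names:
        raise ValidationError(f"unknown PT: {pt!r}")
    n = config.n_reports
    prev = config.target_prevalence
    n_bg = len(config.background_drugs)
    weights = {config.target_generic: prev}
    weights.update({g: (1 - prev) / n_bg for g in config.background_drugs})

    def pair_total(g: str) -> float:
        return sum(_event_prob(config, g, p) for p in config.pt_names)

    w_d = weights[drug]
    a = n * w_d * _event_prob(config, drug, pt)
    ab = n * w_d * pair_total(drug)
    ac = n * sum(w * _event_prob(config, g, pt) for g, w in weights.items())
    total = n * sum(w * pair_total(g) for g, w in weights.items())
    return ExpectedCounts(a=float(a), b=float(ab - a), c=float(ac - a),
                          d=float(total - ab - ac + a))


# ----------------------------------------------------------------------
# generation

def _choice(rng: np.random.Generator, mixture: Mapping[str, float], n: int
            ) -> np.ndarray:
    keys = np.array(list(mixture.keys()), dtype=object)
    probs = np.array(list(mixture.values()), dtype=float)
    probs = probs / probs.sum()
    return keys[rng.choice(len(keys), size=n, p=probs)]


def _date_tokens(dates: np.ndarray) -> np.ndarray:
    """datetime64[D] array -> YYYYMMDD string tokens."""
    text = np.datetime_as_string(dates, unit="D")
    return np.char.replace(text, "-", "")


def generate_frames(config: SyntheticConfig
                    ) -> Tuple[Dict[str, pd.DataFrame], Dict]:
    """Generate the five quarterly tables (FAERS dialect) plus the manifest.

    Returns
    -------
    (frames, manifest)
        frames maps "DEMO"/"DRUG"/"REAC"/"OUTC"/"THER" to DataFrames with
        raw FAERS column headers; manifest records the seed, injected
        signals, expected tables, true duplicate groups and the true target
        cohort.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    n = config.n_reports
    m = len(config.pt_names)

    caseid = np.arange(1_000_001, 1_000_001 + n)
    exposed = rng.random(n) < config.target_prevalence
    bg = np.array(config.background_drugs, dtype=object)
    ps_drug = np.where(exposed, config.target_generic,
                       bg[rng.integers(0, len(bg), n)])

    # --- events: independent Bernoulli per PT given the PS drug ----------
    probs = np.tile(np.asarray(config.pt_probs, dtype=float), (n, 1))
    pt_index = {pt: j for j, pt in enumerate(config.pt_names)}
    for d, pt, rr in config.injected_signals:
        j = pt_index[pt]
        probs[ps_drug == d, j] = min(1.0, rr * config.pt_probs[j])
    event_matrix = rng.random((n, m)) < probs
    rep_rows, pt_cols = np.nonzero(event_matrix)

    # --- dates -----------------------------------------------------------
    d0 = np.datetime64(config.date_start)
    span = int((np.datetime64(config.date_end) - d0).astype(int))
    start_date = d0 + rng.integers(0, span, n)
    onset = rng.exponential(config.onset_scale_days, n).astype(int)
    event_date = start_date + onset
    neg = rng.random(n) < config.negative_interval_rate
    event_date[neg] = start_date[neg] - rng.integers(1, 100, int(neg.sum()))
    fda_date = np.maximum(event_date, start_date) + rng.integers(
        0, config.max_reporting_lag_days + 1, n)

    start_tok = _date_tokens(start_date).astype(object)
    start_tok[rng.random(n) < config.missing_start_date_rate] = ""
    event_tok = _date_tokens(event_date).astype(object)
    partial = rng.random(n) < config.partial_event_date_rate
    trunc_len = rng.choice([4, 6], size=n)
    for i in np.nonzero(partial)[0]:
        event_tok[i] = event_tok[i][: trunc_len[i]]
    event_tok[rng.random(n) < config.missing_event_date_rate] = ""

    # --- demographics ----------------------------------------------------
    sex = _choice(rng, config.sex_probs, n)
    age_years = np.clip(rng.normal(config.age_mean, config.age_sd, n), 0.5, 95.0)
    age_val = np.round(age_years, 0).astype(object)
    age_cod = np.full(n, "YR", dtype=object)
    dec = rng.random(n) < config.age_decade_unit_rate
    age_val[dec] = np.round(age_years[dec] / 10.0, 1)
    age_cod[dec] = "DEC"
    age_missing = rng.random(n) < config.age_missing_rate
    age_val[age_missing] = ""
    age_cod[age_missing] = ""
    country = _choice(rng, config.country_probs, n)
    occp = _choice(rng, config.reporter_probs, n)

    # --- extra drug mentions ----------------------------------------------
    n_extra = rng.poisson(config.concomitant_mean, n)
    extra_rep = np.repeat(np.arange(n), n_extra)
    total_extra = int(n_extra.sum())
    extra_drug = bg[rng.integers(0, len(bg), total_extra)]
    extra_role = _choice(rng, config.extra_role_probs, total_extra)

    # --- outcomes ----------------------------------------------------------
    has_outcome = rng.random(n) < config.outcome_rate
    two_codes = has_outcome & (rng.random(n) < 0.2)
    out_rep = np.concatenate([np.nonzero(has_outcome)[0], np.nonzero(two_codes)[0]])
    out_code = _choice(rng, config.outcome_probs, len(out_rep))

    # --- case versions (duplicates) ----------------------------------------
    n_dup = int(round(config.duplicate_rate * n))
    dup_rows = rng.choice(n, size=n_dup, replace=False) if n_dup else np.array([], int)
    extra_versions = (rng.integers(1, config.max_extra_versions + 1, n_dup)
                      if n_dup else np.array([], int))
    version_rows = [np.arange(n)]
    version_nums = [np.ones(n, dtype=int)]
    for v in range(2, config.max_extra_versions + 2):
        rows = dup_rows[extra_versions >= v - 1]
        version_rows.append(rows)
        version_nums.append(np.full(len(rows), v, dtype=int))
    ridx = np.concatenate(version_rows)
    vnum = np.concatenate(version_nums)
    order = np.lexsort((vnum, ridx))
    ridx, vnum = ridx[order], vnum[order]

    pid = caseid[ridx] * 10 + vnum
    # each later version is received strictly later
    fda_versions = (fda_date[ridx] + (vnum - 1) * 30
                    + np.where(vnum > 1, rng.integers(0, 10, len(vnum)), 0))
    fda_vtok = _date_tokens(fda_versions)

    versions = pd.DataFrame({"ridx": ridx, "primaryid": pid.astype(str),
                             "caseid": caseid[ridx].astype(str),
                             "fda_dt": fda_vtok})

    demo = pd.DataFrame({
        "primaryid": versions["primaryid"],
        "caseid": versions["caseid"],
        "fda_dt": versions["fda_dt"],
        "event_dt": event_tok[ridx],
        "sex": sex[ridx],
        "age": age_val[ridx].astype(str),
        "age_cod": age_cod[ridx],
        "occp_cod": occp[ridx],
        "reporter_country": country[ridx],
        "occr_country": country[ridx],
    })

    def replicate(base: pd.DataFrame) -> pd.DataFrame:
        """Repeat per-case rows once per report version."""
        out = versions[["ridx", "primaryid"]].merge(base, on="ridx", how="inner")
        return out.drop(columns="ridx")

    # PS mention is drug_seq 1; extras follow
    target_display = np.where(rng.random(n) < 0.5,
                              config.target_brand, config.target_generic)
    ps_name = np.where(exposed, target_display, ps_drug).astype(object)
    ps_ai = ps_drug.astype(object)
    drug_base = pd.concat([
        pd.DataFrame({"ridx": np.arange(n), "drug_seq": 1, "role_cod": "PS",
                      "drugname": ps_name, "prod_ai": ps_ai}),
        pd.DataFrame({"ridx": extra_rep,
                      "drug_seq": 2 + _seq_within(extra_rep),
                      "role_cod": extra_role, "drugname": extra_drug,
                      "prod_ai": extra_drug}),
    ], ignore_index=True)
    drug = replicate(drug_base).sort_values(["primaryid", "drug_seq"],
                                            kind="mergesort").reset_index(drop=True)

    reac_base = pd.DataFrame({
        "ridx": rep_rows,
        "pt": np.asarray(config.pt_names, dtype=object)[pt_cols],
    })
    reac = replicate(reac_base).reset_index(drop=True)

    outc_base = pd.DataFrame({"ridx": out_rep, "outc_cod": out_code})
    outc_base = outc_base.drop_duplicates()
    outc = replicate(outc_base).reset_index(drop=True)

    ther_base = pd.DataFrame({"ridx": np.arange(n), "dsg_drug_seq": 1,
                              "start_dt": start_tok})
    ther = replicate(ther_base).reset_index(drop=True)

    frames = {"DEMO": demo, "DRUG": drug, "REAC": reac,
              "OUTC": outc, "THER": ther}

    kept = versions.sort_values(["caseid", "fda_dt", "primaryid"]) \
                   .groupby("caseid").tail(1)
    if n_dup:
        dup_caseids = set(caseid[dup_rows].astype(str))
        grouped = versions[versions["caseid"].isin(dup_caseids)] \
            .groupby("caseid")["primaryid"].apply(sorted)
        duplicate_groups = {str(c): list(v) for c, v in grouped.items()}
    else:
        duplicate_groups = {}
    manifest = {
        "seed": int(config.seed),
        "n_cases": int(n),
        "n_versions": int(len(versions)),
        "injected_signals": [list(s) for s in config.injected_signals],
        "target_names": list(config.target_names()),
        "target_case_count": int(exposed.sum()),
        "target_caseids": [str(c) for c in caseid[exposed]],
        "kept_primaryid_by_caseid": dict(zip(kept["caseid"], kept["primaryid"])),
        "duplicate_groups": duplicate_groups,
        "expected_tables": {
            f"{d}|{pt}": dataclasses.asdict(expected_table(config, d, pt))
            for d, pt, _ in config.injected_signals
        },
    }
    return frames, manifest


def _seq_within(rep: np.ndarray) -> np.ndarray:
    """0-based running index within consecutive equal values of *rep*."""
    if len(rep) == 0:
        return np.zeros(0, dtype=int)
    starts = np.r_[0, np.nonzero(np.diff(rep))[0] + 1]
    counts = np.diff(np.r_[starts, len(rep)])
    return np.arange(len(rep)) - np.repeat(starts, counts)


def generate(config: SyntheticConfig, out_dir) -> Dict[str, Path]:
    """Write the quarterly file set, PT->SOC map and manifest to *out_dir*.

    Returns the paths written, keyed by table kind plus ``"pt_soc_map"`` and
    ``"manifest"``.
    """
    config.validate()  # fail before creating any file
    frames, manifest = generate_frames(config)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths: Dict[str, Path] = {}
    for kind, frame in frames.items():
        path = out / f"{kind}.txt"
        frame.to_csv(path, sep=DELIMITER, index=False)
        paths[kind] = path
    map_path = out / "pt_soc_map.tsv"
    write_pt_soc_map(PtSocMap(entries=config.pt_soc), map_path)
    paths["pt_soc_map"] = map_path
    manifest_path = out / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=1, sort_keys=True))
    paths["manifest"] = manifest_path
    return paths
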