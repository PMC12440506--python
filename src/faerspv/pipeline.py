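"""End-to-end orchestration: read -> dedup -> cohort -> signals -> onset.

``run_pipeline`` executes the full analysis on a directory of FAERS-dialect
quarterly tables and writes the standard outputs: the cohort descriptive
table, full and jointly-positive signal tables at PT and SOC level (both
machine-readable full precision and a 2-decimal display layout), and the
time-to-onset summary.  Every stage logs its input/output record counts and
any stage validation error aborts naming the stage.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Tuple

import pandas as pd
import yaml

from . import cohort as cohort_mod
from . import dedup as dedup_mod
from . import io as io_mod
from . import onset as onset_mod
from .signals import Disproportionality, DisproportionalityResults, SignalCriteria

logger = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    """A stage failed; the message names the stage."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage '{stage}' failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class PipelineConfig:
    """Configuration for one full analysis run."""

    input_dir: str
    pt_soc_map: str
    output_dir: str
    target_names: Tuple[str, ...] = ("OZANIMOD", "ZEPOSIA")
    role: str = "PS"
    substring_match: bool = False
    counting_unit: str = "pair"          # or "report"
    criteria: SignalCriteria = field(default_factory=SignalCriteria)
    continuity: bool = False
    country_field: str = "reporter_country"   # or "occr_country"
    top_countries: int = 2
    onset_start_source: str = "ther"     # or "drug"
    output_sep: str = "\t"

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        crit = data.pop("criteria", None)
        cfg = cls(**data)
        if crit:
            cfg.criteria = SignalCriteria(**crit)
        if cfg.target_names is not None:
            cfg.target_names = tuple(cfg.target_names)
        return cfg


@dataclass
class PipelineResult:
    """Bundle of everything one run produced."""

    cohort_summary: cohort_mod.CohortSummary
    pt_results: DisproportionalityResults
    soc_results: DisproportionalityResults
    onset_summary: onset_mod.OnsetSummary
    counts: Dict[str, int]
    log: List[str]
    output_paths: Dict[str, Path]


def _stage(log: List[str], name: str, **info) -> None:
    line = f"stage={name} " + " ".join(f"{k}={v}" for k, v in info.items())
    log.append(line)
    logger.info(line)


def run_pipeline(config: PipelineConfig) -> PipelineResult:
    """Run the full analysis; see module docstring for the stage order."""
    log: List[str] = []
    counts: Dict[str, int] = {}
    in_dir = Path(config.input_dir)
    out_dir = Path(config.output_dir)

    def stage(name, fn):
        try:
            return fn()
        except Exception as exc:  # noqa: BLE001 - re-raised with stage context
            raise PipelineError(name, exc) from exc

    # --- read ----------------------------------------------------------
    def _read():
        tables = {}
        for kind in io_mod.TABLE_KINDS:
            path = in_dir / f"{kind}.txt"
            tables[kind] = io_mod.read_table(path, kind)
            _stage(log, "read", table=kind, rows=len(tables[kind]))
        mapping = io_mod.read_pt_soc_map(config.pt_soc_map)
        _stage(log, "read", table="pt_soc_map", entries=len(mapping))
        return tables, mapping

    tables, mapping = stage("read", _read)
    counts["reports_in"] = len(tables["DEMO"])

    # --- dedup ----------------------------------------------------------
    def _dedup():
        kept, dropped = dedup_mod.deduplicate(tables["DEMO"])
        _stage(log, "dedup", reports_in=len(tables["DEMO"]),
               reports_kept=len(kept), dropped=dropped)
        return kept

    demo = stage("dedup", _dedup)
    counts["reports_after_dedup"] = len(demo)
    kept_ids = set(demo["primaryid"])
    drug = dedup_mod.filter_to_reports(tables["DRUG"], kept_ids)
    reac = dedup_mod.filter_to_reports(tables["REAC"], kept_ids)
    outc = dedup_mod.filter_to_reports(tables["OUTC"], kept_ids)
    ther = dedup_mod.filter_to_reports(tables["THER"], kept_ids)

    # --- cohort ----------------------------------------------------------
    def _cohort():
        ids = cohort_mod.select_target_reports(
            demo, drug, config.target_names, role=config.role,
            substring=config.substring_match)
        _stage(log, "cohort", target_reports=len(ids))
        demo_cohort = demo[demo["primaryid"].isin(set(ids))]
        summary = cohort_mod.summarize_characteristics(
            demo_cohort, outc, country_field=config.country_field,
            top_countries=config.top_countries)
        return ids, summary

    target_ids, summary = stage("cohort", _cohort)
    counts["cohort_size"] = len(target_ids)
    assert counts["reports_in"] >= counts["reports_after_dedup"] >= counts["cohort_size"]

    # --- signals ----------------------------------------------------------
    def _signals():
        pt_model = Disproportionality.from_events(
            reac, target_ids, level="pt", unit=config.counting_unit)
        pt_res = pt_model.fit(config.criteria, continuity=config.continuity)
        soc_model = Disproportionality.from_events(
            reac, target_ids, level="soc", pt_soc_map=mapping,
            unit=config.counting_unit)
        soc_res = soc_model.fit(config.criteria, continuity=config.continuity)
        _stage(log, "signals", pt_terms=len(pt_res.frame),
               pt_positive=len(pt_res.signals),
               soc_terms=len(soc_res.frame),
               soc_positive=len(soc_res.signals),
               unmapped_pts=len(soc_res.unmapped_pts))
        return pt_res, soc_res

    pt_res, soc_res = stage("signals", _signals)

    # --- onset ------------------------------------------------------------
    def _onset():
        records = onset_mod.compute_onset(
            demo, drug, ther, target_ids, config.target_names,
            role=config.role, start_source=config.onset_start_source)
        osum = onset_mod.summarize_onset(records)
        _stage(log, "onset", records=len(records), evaluable=osum.evaluable_n,
               **{f"excluded_{k}": v for k, v in osum.excluded.items()})
        return osum

    onset_summary = stage("onset", _onset)

    # --- write ------------------------------------------------------------
    def _write():
        out_dir.mkdir(parents=True, exist_ok=True)
        sep = config.output_sep
        paths: Dict[str, Path] = {}

        def emit(name: str, frame: pd.DataFrame, full_precision: bool = False):
            path = out_dir / name
            if full_precision:
                frame.to_csv(path, sep=sep, index=False)
            else:
                io_mod.write_results_table(frame, path, sep=sep)
            paths[name] = path

        emit("cohort_summary.tsv", summary.to_frame())
        for label, res in (("pt", pt_res), ("soc", soc_res)):
            emit(f"{label}_signals.tsv", res.frame, full_precision=True)
            emit(f"{label}_signals_display.tsv", res.summary())
            emit(f"{label}_signals_positive.tsv", res.signals, full_precision=True)
        emit("onset_summary.tsv", onset_summary.to_frame())
        if soc_res.unmapped_pts:
            (out_dir / "unmapped_pts.txt").write_text(
                "\n".join(sorted(soc_res.unmapped_pts)) + "\n")
            paths["unmapped_pts.txt"] = out_dir / "unmapped_pts.txt"
        (out_dir / "run_log.txt").write_text("\n".join(log) + "\n")
        paths["run_log.txt"] = out_dir / "run_log.txt"
        return paths

    paths = stage("write", _write)

    return PipelineResult(cohort_summary=summary, pt_results=pt_res,
                          soc_results=soc_res, onset_summary=onset_summary,
                          counts=counts, log=log, output_paths=paths)
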