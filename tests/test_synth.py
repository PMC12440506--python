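import json
import math

import pytest

from faerspv.contingency import build_pt_tables
from faerspv.dedup import deduplicate
from faerspv.io import ValidationError, read_table
from faerspv.synth import (SyntheticConfig, expected_table,
                           generate, generate_frames)


def test_report_count_without_duplicates(tmp_path):
    paths = generate(SyntheticConfig(n_reports=100, seed=0, duplicate_rate=0.0),
                     tmp_path)
    demo_lines = paths["DEMO"].read_text().strip().splitlines()
    assert len(demo_lines) - 1 == 100


def test_same_seed_gives_byte_identical_files(tmp_path):
    cfg = SyntheticConfig(n_reports=300, seed=11)
    p1 = generate(cfg, tmp_path / "a")
    p2 = generate(cfg, tmp_path / "b")
    for kind in ("DEMO", "DRUG", "REAC", "OUTC", "THER", "pt_soc_map"):
        assert p1[kind].read_bytes() == p2[kind].read_bytes()


def test_different_seed_changes_output(tmp_path):
    a = generate(SyntheticConfig(n_reports=300, seed=1), tmp_path / "a")
    b = generate(SyntheticConfig(n_reports=300, seed=2), tmp_path / "b")
    assert a["DEMO"].read_bytes() != b["DEMO"].read_bytes()


def test_duplicate_versions_share_caseid_with_later_receipt():
    frames, manifest = generate_frames(SyntheticConfig(n_reports=500, seed=4,
                                                       duplicate_rate=0.2))
    demo = frames["DEMO"]
    for caseid, pids in manifest["duplicate_groups"].items():
        group = demo[demo["caseid"] == caseid].sort_values("primaryid")
        assert len(group) == len(pids) >= 2
        fda = list(group["fda_dt"])
        assert fda == sorted(fda) and len(set(fda)) == len(fda)
    # dedup recovers exactly the manifest's kept version
    kept, _ = deduplicate(demo.assign(event_dt="", sex="unknown"))
    expected = manifest["kept_primaryid_by_caseid"]
    assert dict(zip(kept["caseid"], kept["primaryid"])) == expected


def test_invalid_configs_rejected_before_writing(tmp_path):
    bad = [
        SyntheticConfig(n_reports=0),
        SyntheticConfig(target_prevalence=1.5),
        SyntheticConfig(injected_signals=(("NO_SUCH_DRUG", "PT_030", 5.0),)),
        SyntheticConfig(injected_signals=(("OZANIMOD", "PT_030", -1.0),)),
        SyntheticConfig(sex_probs={"F": 0.5, "M": 0.2, "UNK": 0.2}),
        SyntheticConfig(duplicate_rate=1.2),
    ]
    for cfg in bad:
        with pytest.raises(ValidationError):
            generate(cfg, tmp_path / "out")
        assert not (tmp_path / "out").exists()


class TestExpectedTable:
    def test_rr_one_implies_unit_ror(self):
        cfg = SyntheticConfig(injected_signals=())
        exp = expected_table(cfg, "OZANIMOD", "PT_030")
        assert exp.ror == pytest.approx(1.0)
        assert exp.ebgm == pytest.approx(1.0)

    def test_direct_expectation_arithmetic(self):
        # one-PT design: prevalence 0.1, p = 0.01, RR = 5, n = 1e5
        # E[a] = n * 0.1 * min(1, 5 * 0.01) = 500
        cfg = SyntheticConfig(
            n_reports=100_000, target_prevalence=0.1,
            pt_names=("PT_001",), pt_soc={"PT_001": "SOC_01"},
            pt_probs=(0.01,),
            injected_signals=(("OZANIMOD", "PT_001", 5.0),))
        exp = expected_table(cfg, "OZANIMOD", "PT_001")
        assert exp.a == pytest.approx(500.0)
        assert exp.c == pytest.approx(100_000 * 0.9 * 0.01)

    def test_expectations_conserve_target_pair_total(self):
        cfg = SyntheticConfig(n_reports=10_000)
        total = sum(expected_table(cfg, "OZANIMOD", pt).a for pt in cfg.pt_names)
        ab = expected_table(cfg, "OZANIMOD", cfg.pt_names[0])
        assert ab.a + ab.b == pytest.approx(total)

    def test_unknown_pair_is_an_error(self):
        cfg = SyntheticConfig()
        with pytest.raises(ValidationError):
            expected_table(cfg, "OZANIMOD", "NOT_A_PT")
        with pytest.raises(ValidationError):
            expected_table(cfg, "NOT_A_DRUG", "PT_001")


def test_null_generator_ratios_concentrate_near_one():
    """With RR = 1 everywhere the target vs background reporting proportions
    agree to within 3 binomial standard errors at n = 50 000."""
    cfg = SyntheticConfig(n_reports=50_000, seed=17, injected_signals=(),
                          duplicate_rate=0.0)
    frames, _ = generate_frames(cfg)
    drug = frames["DRUG"]
    target = set(drug.loc[(drug["role_cod"] == "PS")
                          & (drug["prod_ai"] == "OZANIMOD"), "primaryid"])
    events = frames["REAC"].rename(columns=str.lower)
    tables = build_pt_tables(events, target)
    checked = 0
    for pt, t in tables.items():
        if t.a < 10:
            continue
        p_t = t.a / (t.a + t.b)
        p_b = t.c / (t.c + t.d)
        se = math.sqrt(p_t * (1 - p_t) / (t.a + t.b)
                       + p_b * (1 - p_b) / (t.c + t.d))
        assert abs(p_t - p_b) <= 3 * se, pt
        checked += 1
    assert checked >= 10


def test_generated_files_parse_through_io(tmp_path):
    paths = generate(SyntheticConfig(n_reports=200, seed=5), tmp_path)
    for kind in ("DEMO", "DRUG", "REAC", "OUTC", "THER"):
        frame = read_table(paths[kind], kind)
        assert len(frame) > 0
    manifest = json.loads(paths["manifest"].read_text())
    assert manifest["seed"] == 5
    assert manifest["injected_signals"] == [["OZANIMOD", "PT_030", 5.0]]
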