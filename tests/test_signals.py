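import math

import pytest
from hypothesis import given
from hypothesis import strategies as st

from faerspv.contingency import ContingencyTable
from faerspv.signals import (Disproportionality, SignalCriteria, bcpnn_ic,
                             evaluate_signals, mgps_ebgm, prr, ror)


def oracle(a, b, c, d):
    """Independent hand-arithmetic implementation of all four estimators."""
    n = a + b + c + d
    s = math.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    ror_ = (a * d) / (b * c)
    prr_ = (a / (a + b)) / (c / (c + d))
    chi2 = n * (a * d - b * c) ** 2 / ((a + b) * (c + d) * (a + c) * (b + d))
    ebgm = a * n / ((a + b) * (a + c))
    return {
        "ror": ror_,
        "ror_lo": math.exp(math.log(ror_) - 1.96 * s),
        "ror_hi": math.exp(math.log(ror_) + 1.96 * s),
        "prr": prr_,
        "chi2": chi2,
        "ebgm": ebgm,
        "ebgm05": math.exp(math.log(ebgm) - 1.64 * s),
        "ic": math.log2(ebgm),
        "ic025": math.log2(ebgm) - 2 * s / math.log(2),
    }


T = ContingencyTable(10, 90, 100, 9900)
NULL = ContingencyTable(5, 5, 5, 5)


class TestPointEstimates:
    def test_reference_table_to_printed_precision(self):
        # frozen from the hand-arithmetic oracle on (10, 90, 100, 9900)
        r, lo, hi = ror(T)
        assert round(r, 2) == 11.00 and round(lo, 2) == 5.56
        p, chi2 = prr(T)
        assert round(p, 2) == 10.00 and round(chi2, 2) == 74.45
        ic, ic025 = bcpnn_ic(T)
        assert round(ic, 2) == 3.20 and round(ic025, 2) == 2.19
        e, e05 = mgps_ebgm(T)
        assert round(e, 2) == 9.18 and round(e05, 2) == 5.19

    def test_null_table(self):
        assert ror(NULL)[0] == pytest.approx(1.0)
        p, chi2 = prr(NULL)
        assert p == pytest.approx(1.0) and chi2 == pytest.approx(0.0)
        assert bcpnn_ic(NULL)[0] == pytest.approx(0.0)
        assert mgps_ebgm(NULL)[0] == pytest.approx(1.0)

    def test_zero_cells_yield_undefined_markers_not_zero(self):
        t = ContingencyTable(0, 10, 5, 100)
        assert all(math.isnan(x) for x in ror(t))
        assert all(math.isnan(x) for x in bcpnn_ic(t))
        assert all(math.isnan(x) for x in mgps_ebgm(t))

    def test_estimates_strictly_increase_in_a(self):
        prev = None
        for a in (1, 2, 5, 10, 40):
            t = ContingencyTable(a, 90, 100, 9900)
            cur = (ror(t)[0], prr(t)[0], bcpnn_ic(t)[0], mgps_ebgm(t)[0])
            if prev is not None:
                assert all(x > y for x, y in zip(cur, prev))
            prev = cur


small_counts = st.integers(min_value=1, max_value=500)


@given(small_counts, small_counts, small_counts, small_counts)
def test_closed_forms_match_independent_oracle(a, b, c, d):
    t = ContingencyTable(a, b, c, d)
    exp = oracle(a, b, c, d)
    r, lo, hi = ror(t)
    p, chi2 = prr(t)
    ic, ic025 = bcpnn_ic(t)
    e, e05 = mgps_ebgm(t)
    got = {"ror": r, "ror_lo": lo, "ror_hi": hi, "prr": p, "chi2": chi2,
           "ebgm": e, "ebgm05": e05, "ic": ic, "ic025": ic025}
    for key, val in exp.items():
        assert got[key] == pytest.approx(val, rel=1e-12), key


@given(small_counts, small_counts, small_counts, small_counts)
def test_ror_prr_sign_coherence(a, b, c, d):
    """ror/prr = (1 + a/b)/(1 + c/d), so both sit on the same side of 1."""
    t = ContingencyTable(a, b, c, d)
    r, p = ror(t)[0], prr(t)[0]
    if r > 1:
        assert r > p > 1 or p == pytest.approx(1.0)
    elif r < 1:
        assert r < p < 1 or p == pytest.approx(1.0)
    else:
        assert p == pytest.approx(1.0)


@given(small_counts, small_counts, small_counts, small_counts)
def test_ic_is_log2_of_ebgm(a, b, c, d):
    t = ContingencyTable(a, b, c, d)
    assert bcpnn_ic(t)[0] == pytest.approx(math.log2(mgps_ebgm(t)[0]), rel=1e-12)


def test_interval_bounds_shrink_on_scaled_tables():
    widths = []
    for k in (1, 10, 100, 1000):
        t = ContingencyTable(10 * k, 90 * k, 100 * k, 9900 * k)
        r, lo, hi = ror(t)
        e, e05 = mgps_ebgm(t)
        ic, ic025 = bcpnn_ic(t)
        widths.append((hi - lo, e - e05, ic - ic025))
    for later, earlier in zip(widths[1:], widths[:-1]):
        assert all(x < y for x, y in zip(later, earlier))


class TestSignalEvaluation:
    def test_reference_table_flags_all_four(self):
        frame = evaluate_signals({"X": T})
        row = frame.iloc[0]
        assert row[["ror_flag", "prr_flag", "ic_flag", "ebgm_flag",
                    "joint_flag"]].all()

    def test_case_count_gate_beats_huge_ror(self):
        t = ContingencyTable(2, 1, 1, 10000)  # enormous ROR but a < 3
        row = evaluate_signals({"X": t}).iloc[0]
        assert row["ror"] > 100
        assert not row["ror_flag"] and not row["joint_flag"]

    def test_null_table_flags_nothing(self):
        row = evaluate_signals({"X": NULL}).iloc[0]
        assert not row[["ror_flag", "prr_flag", "ic_flag", "ebgm_flag",
                        "joint_flag"]].any()

    def test_joint_flag_is_conjunction(self):
        tables = {f"T{i}": ContingencyTable(a, 90, 100, 9900)
                  for i, a in enumerate((1, 3, 10, 50))}
        frame = evaluate_signals(tables)
        expected = (frame["ror_flag"] & frame["prr_flag"]
                    & frame["ic_flag"] & frame["ebgm_flag"])
        assert (frame["joint_flag"] == expected).all()

    def test_continuity_option_rescues_zero_cells(self):
        t = ContingencyTable(5, 10, 0, 100)
        plain = evaluate_signals({"X": t}).iloc[0]
        rescued = evaluate_signals({"X": t}, continuity=True).iloc[0]
        assert math.isnan(plain["ror"])
        assert math.isfinite(rescued["ror"])
        assert rescued["a"] == 5  # flags still gate on the raw count

    def test_invalid_criteria_rejected(self):
        with pytest.raises(ValueError):
            evaluate_signals({"X": T}, SignalCriteria(prr_min=math.inf))


class TestModelInterface:
    def test_fit_returns_sorted_results_with_signals_subset(self):
        import pandas as pd
        events = pd.DataFrame({
            "primaryid": ["r1", "r1", "r2", "r3", "r4", "r5"],
            "pt": ["A", "B", "A", "B", "B", "B"],
        })
        res = Disproportionality.from_events(events, ["r1"]).fit()
        assert list(res.frame["term"]) == sorted(
            res.frame["term"], key=lambda t: (-res.frame.set_index("term").loc[t, "a"], t))
        assert res.signals["joint_flag"].all() if len(res.signals) else True

    def test_summary_layout_rounds_to_two_decimals(self):
        res = Disproportionality({"HEADACHE": T}).fit()
        display = res.summary()
        assert display.loc[0, "ROR (95% CI)"] == "11.00 (5.56-21.76)"
        assert display.loc[0, "PRR (chi2)"] == "10.00 (74.45)"
        assert display.loc[0, "EBGM (EBGM05)"] == "9.18 (5.19)"
        assert display.loc[0, "IC (IC025)"] == "3.20 (2.19)"

    def test_soc_level_requires_mapping(self):
        import pandas as pd
        events = pd.DataFrame({"primaryid": ["r1"], "pt": ["A"]})
        with pytest.raises(ValueError):
            Disproportionality.from_events(events, ["r1"], level="soc")
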