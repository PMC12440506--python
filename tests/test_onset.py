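import pandas as pd
from hypothesis import given
from hypothesis import strategies as st

from faerspv.onset import ONSET_BINS, bin_label, compute_onset, summarize_onset

NAMES = {"OZANIMOD", "ZEPOSIA"}


def _inputs(event_dt, start_dt, ther_start=None):
    demo = pd.DataFrame({"primaryid": ["1"], "caseid": ["1"],
                         "fda_dt": ["20210601"], "event_dt": [event_dt]})
    drug = pd.DataFrame({"primaryid": ["1"], "drug_seq": pd.array([1], dtype="Int64"),
                         "role_code": ["PS"], "drugname": ["ZEPOSIA"],
                         "active_ingredient": ["OZANIMOD"], "start_dt": [start_dt]})
    ther = None
    if ther_start is not None:
        ther = pd.DataFrame({"primaryid": ["1"], "drug_seq": pd.array([1], dtype="Int64"),
                             "start_dt": [ther_start]})
    return demo, drug, ther


def _one(event_dt, start_dt, ther_start=None, **kw):
    demo, drug, ther = _inputs(event_dt, start_dt, ther_start)
    return compute_onset(demo, drug, ther, ["1"], NAMES, **kw).iloc[0]


class TestComputeOnset:
    def test_calendar_day_difference(self):
        rec = _one("20210131", "20210101")
        assert rec["onset_days"] == 30 and rec["status"] == ""

    def test_event_before_start_is_excluded_as_input_error(self):
        rec = _one("20210215", "20210301")
        assert rec["status"] == "negative_interval"
        assert pd.isna(rec["onset_days"])

    def test_same_day_start_and_event_is_day_zero(self):
        rec = _one("20210101", "20210101")
        assert rec["onset_days"] == 0
        assert bin_label(0) == "<=30 d"

    def test_partial_and_missing_dates_get_statuses(self):
        assert _one("202101", "20210101")["status"] == "partial_date"
        assert _one("", "20210101")["status"] == "missing_date"
        assert _one("20210131", "")["status"] == "missing_date"
        assert _one("20210131", "202101")["status"] == "partial_date"

    def test_therapy_table_preferred_over_drug_column(self):
        rec = _one("20210131", "20210110", ther_start="20210101")
        assert rec["onset_days"] == 30

    def test_drug_column_fallback_when_therapy_start_absent(self):
        rec = _one("20210131", "20210101", ther_start="")
        assert rec["onset_days"] == 30

    def test_drug_source_can_be_forced(self):
        rec = _one("20210131", "20210101", ther_start="20210111",
                   start_source="drug")
        assert rec["onset_days"] == 30

    def test_earliest_complete_start_among_multiple_ps_mentions(self):
        demo = pd.DataFrame({"primaryid": ["1"], "caseid": ["1"],
                             "fda_dt": ["20210601"], "event_dt": ["20210301"]})
        drug = pd.DataFrame({
            "primaryid": ["1", "1"], "drug_seq": pd.array([1, 2], dtype="Int64"),
            "role_code": ["PS", "PS"], "drugname": ["ZEPOSIA", "OZANIMOD"],
            "active_ingredient": ["", ""], "start_dt": ["20210201", "20210101"]})
        rec = compute_onset(demo, drug, None, ["1"], NAMES).iloc[0]
        assert rec["onset_days"] == 59  # from the earliest exposure


class TestSummarize:
    def test_direct_binning(self):
        records = pd.DataFrame({"primaryid": ["1", "2", "3"],
                                "onset_days": pd.array([5, 45, 400], dtype="Int64"),
                                "status": ["", "", ""]})
        s = summarize_onset(records)
        assert list(s.bins.values()) == [1, 1, 0, 0, 0, 1]
        assert s.evaluable_n == 3

    def test_published_bin_shares(self):
        # bin counts (568, 171, 138, 223, 204, 195) over 1499 evaluable reports
        counts = [568, 171, 138, 223, 204, 195]
        reps = [15, 45, 75, 120, 250, 400]
        days = [d for k, d in zip(counts, reps) for _ in range(k)]
        records = pd.DataFrame({"primaryid": [str(i) for i in range(len(days))],
                                "onset_days": pd.array(days, dtype="Int64"),
                                "status": [""] * len(days)})
        s = summarize_onset(records)
        assert s.evaluable_n == 1499
        pcts = s.percentages()
        assert pcts["<=30 d"] == 37.89
        assert pcts[">360 d"] == 13.01

    def test_all_excluded_gives_empty_summary(self):
        records = pd.DataFrame({"primaryid": ["1"],
                                "onset_days": pd.array([None], dtype="Int64"),
                                "status": ["missing_date"]})
        s = summarize_onset(records)
        assert s.evaluable_n == 0 and s.median_days is None
        assert all(v == 0 for v in s.bins.values())

    def test_conservation_of_records(self):
        records = pd.DataFrame({
            "primaryid": list("12345"),
            "onset_days": pd.array([3, None, None, None, 100], dtype="Int64"),
            "status": ["", "missing_date", "partial_date", "negative_interval", ""],
        })
        s = summarize_onset(records)
        assert s.evaluable_n + sum(s.excluded.values()) == len(records)

    def test_lower_median(self):
        records = pd.DataFrame({"primaryid": list("1234"),
                                "onset_days": pd.array([1, 2, 3, 4], dtype="Int64"),
                                "status": [""] * 4})
        assert summarize_onset(records).median_days == 2


@given(st.integers(min_value=0, max_value=1000))
def test_binning_is_exhaustive_and_exclusive(days):
    matches = [label for label, lo, hi in ONSET_BINS
               if days >= lo and (hi is None or days <= hi)]
    assert len(matches) == 1
    assert bin_label(days) == matches[0]
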