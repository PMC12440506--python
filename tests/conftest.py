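from pathlib import Path

import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci", deadline=None, derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


def write_faers(path: Path, header: str, lines) -> Path:
    """Write a small $-delimited FAERS-style file."""
    body = "\n".join([header] + list(lines)) + "\n"
    path.write_text(body)
    return path


@pytest.fixture
def demo_file(tmp_path):
    header = ("primaryid$caseid$fda_dt$event_dt$sex$age$age_cod$occp_cod$"
              "reporter_country$occr_country")
    return write_faers(tmp_path / "DEMO.txt", header, [
        "1111$111$20210101$202103$F$45$YR$MD$US$US",
        "2221$222$20210215$20210310$M$5$DEC$CN$DE$DE",
    ])


@pytest.fixture
def demo_frame():
    return pd.DataFrame({
        "primaryid": ["1111", "1112", "1113", "2221"],
        "caseid": ["111", "111", "111", "222"],
        "fda_dt": ["20210101", "20210301", "20210301", "20200601"],
        "event_dt": ["", "", "", "20200501"],
        "sex": ["female", "female", "female", "male"],
        "age_years": [45.0, 45.0, 45.0, 62.0],
        "reporter_country": ["US"] * 4,
        "occr_country": ["US"] * 4,
        "reporter_type": ["physician"] * 4,
        "report_year": pd.array([2021, 2021, 2021, 2020], dtype="Int64"),
    })


@pytest.fixture
def pt_map_file(tmp_path):
    path = tmp_path / "pt_soc.tsv"
    path.write_text("pt\tsoc\nHEADACHE\tNervous system disorders\n"
                    "DIZZINESS\tNervous system disorders\n"
                    "NAUSEA\tGastrointestinal disorders\n")
    return path
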