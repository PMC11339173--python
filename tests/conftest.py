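import numpy as np
import pandas as pd
import pytest

from synthits.registry_io import (
    FIVE_YEAR_GROUPS,
    CauseDefinition,
    PopulationTable,
    StudyConfig,
    who_standard_population,
)


@pytest.fixture(scope="session")
def causes():
    """Cardiovascular cause definitions used throughout the tests."""
    defs = {
        "ihd": CauseDefinition("ihd", icd10_ranges=("I20-I25",)),
        "ami": CauseDefinition("ami", icd10_ranges=("I21",)),
        "stroke": CauseDefinition("stroke", icd10_ranges=("I61-I64", "I67")),
    }
    defs["ihd_stroke"] = CauseDefinition("ihd_stroke",
                                         composite_of=("ihd", "stroke"))
    return defs


@pytest.fixture
def study_config(causes):
    return StudyConfig(study_start="2007-01", study_end="2017-12",
                       policy_month="2013-03", causes=dict(causes))


@pytest.fixture(scope="session")
def pop_table():
    """Flat population: 50 000 per (group, sex), every study year."""
    rows = [
        {"year": year, "age_group": g, "sex": sex, "population": 50_000}
        for year in range(2007, 2018)
        for g in FIVE_YEAR_GROUPS
        for sex in ("M", "F")
    ]
    return PopulationTable(pd.DataFrame(rows))


@pytest.fixture(scope="session")
def who_std():
    return who_standard_population()


@pytest.fixture
def write_events_csv(tmp_path):
    def _write(rows, header="date,icd10,age,sex,count", name="events.csv"):
        path = tmp_path / name
        path.write_text("\n".join([header] + rows) + "\n")
        return path
    return _write
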