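from datetime import date

import numpy as np
import pandas as pd
import pytest

from previndex.registry import LifeTable, PatientRecord, PopulationTable

INDEX_DATE = date(2013, 1, 1)


@pytest.fixture
def index_date():
    return INDEX_DATE


@pytest.fixture
def flat_life_table():
    """Life table with survival 1 everywhere (no background mortality)."""
    rows = [
        (sex, age, year, 1.0)
        for sex in ("male", "female")
        for age in range(0, 100)
        for year in range(1950, 2014)
    ]
    return LifeTable(pd.DataFrame(rows, columns=["sex", "age", "year", "annual_survival"]))


@pytest.fixture
def simple_life_table():
    """Constant 0.98 annual survival at every age and year."""
    rows = [
        (sex, age, year, 0.98)
        for sex in ("male", "female")
        for age in range(100)
        for year in range(1950, 2014)
    ]
    return LifeTable(pd.DataFrame(rows, columns=["sex", "age", "year", "annual_survival"]))


@pytest.fixture
def small_population():
    rows = [
        (sex, "0-99", year, 100_000)
        for sex in ("male", "female")
        for year in range(1950, 2014)
    ]
    return PopulationTable(pd.DataFrame(rows, columns=["sex", "age_group", "year", "count"]))


def make_record(
    person_id="p1",
    sex="male",
    site="colon",
    date_dx=date(2005, 6, 1),
    age_dx=60,
    vital_status="alive",
    date_end=INDEX_DATE,
):
    return PatientRecord(
        person_id=person_id, sex=sex, site=site, date_dx=date_dx,
        age_dx=age_dx, vital_status=vital_status, date_end=date_end,
    )
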