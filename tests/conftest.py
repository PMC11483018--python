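import datetime as dt

import pandas as pd
import pytest

from ppdwear import (
    AnalysisConfig,
    Cohort,
    CohortAssignment,
    PersonRecord,
    SyntheticConfig,
    generate_cohort,
)

DELIVERY = dt.date(2020, 3, 15)


@pytest.fixture
def person():
    return PersonRecord(
        person_id="p1",
        age_at_index=32.0,
        race_ethnicity="White non-Hispanic",
        pregnancy_start_date=DELIVERY - dt.timedelta(days=280),
        delivery_date=DELIVERY,
        first_fitbit_date=dt.date(2016, 1, 1),
    )


@pytest.fixture
def config():
    return AnalysisConfig()


def assignment_for(person, onset_days, cohort=Cohort.PPD):
    index = person.delivery_date + dt.timedelta(days=onset_days)
    return CohortAssignment(
        person_id=person.person_id,
        cohort=cohort,
        index_date=index,
        days_delivery_to_index=onset_days,
    )


@pytest.fixture(scope="session")
def small_cohort():
    """A small but complete synthetic cohort shared across pipeline tests."""
    return generate_cohort(SyntheticConfig(n_ppd=6, n_nonppd=10, seed=42))


def daily_frame(rows):
    """Build a daily wear DataFrame from (person_id, date, hours, worn, sleep)."""
    columns = [
        "person_id", "date", "hours_worn", "steps_total",
        "worn", "sleep_worn", "valid_day",
    ]
    if not rows:
        return pd.DataFrame(columns=columns)
    return pd.DataFrame(
        [
            {
                "person_id": pid,
                "date": date,
                "hours_worn": hours,
                "steps_total": hours * 100,
                "worn": worn,
                "sleep_worn": sleep,
                "valid_day": False,
            }
            for pid, date, hours, worn, sleep in rows
        ]
    )
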