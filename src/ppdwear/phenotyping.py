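"""EHR-driven cohort phenotyping and pregnancy-phase timeline segmentation.

A woman belongs to the PPD cohort when her health record shows, within 24
months (730 days) after delivery, at least one of: a postpartum-depression
diagnosis, a depression diagnosis, or antidepressant drug exposure. Her
index date is the earliest qualifying event. Women without a qualifying
event form the non-PPD cohort; their timelines are aligned through a
PPD-equivalent index placed 58 days after delivery — the PPD cohort's
median diagnosis delay.

Each woman's calendar is then segmented into four analysis periods:

* pre-pregnancy — from 730 days before the index date up to the day before
  pregnancy start;
* pregnancy — pregnancy start through delivery;
* postpartum — the day after delivery up to 15 days before the index date
  (i.e. before the PPD window opens);
* PPD window — 14 days before the index through 30 days after for the PPD
  cohort (45 days); index through index + 30 for the non-PPD cohort
  (31 days), the preceding fortnight being excluded from every denominator
  because those women did not experience depression onset.

Periods are closed day intervals and never overlap within one person.
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass
from enum import Enum
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .config import AnalysisConfig, ConfigurationError

__all__ = [
    "EventClass",
    "Cohort",
    "Period",
    "PersonRecord",
    "EHREvent",
    "CohortAssignment",
    "PeriodAssignment",
    "PhenotypingError",
    "classify_ppd",
    "ppd_equivalent_index",
    "segment_periods",
    "filter_eligible",
]


class PhenotypingError(ValueError):
    """Raised when a person's record cannot be phenotyped."""


class EventClass(str, Enum):
    PPD_DIAGNOSIS = "PPD_DIAGNOSIS"
    DEPRESSION_DIAGNOSIS = "DEPRESSION_DIAGNOSIS"
    ANTIDEPRESSANT_EXPOSURE = "ANTIDEPRESSANT_EXPOSURE"
    DELIVERY = "DELIVERY"
    PREGNANCY_START = "PREGNANCY_START"


#: Event classes that qualify a woman for the PPD cohort.
QUALIFYING_CLASSES = frozenset(
    {
        EventClass.PPD_DIAGNOSIS,
        EventClass.DEPRESSION_DIAGNOSIS,
        EventClass.ANTIDEPRESSANT_EXPOSURE,
    }
)


class Cohort(str, Enum):
    PPD = "PPD"
    NON_PPD = "non_PPD"


class Period(str, Enum):
    PRE_PREGNANCY = "pre_pregnancy"
    PREGNANCY = "pregnancy"
    POSTPARTUM = "postpartum"
    PPD_WINDOW = "ppd"


@dataclass(frozen=True)
class PersonRecord:
    """One woman: identifiers, demographics and anchor dates."""

    person_id: str
    age_at_index: float
    race_ethnicity: str
    pregnancy_start_date: dt.date
    delivery_date: dt.date
    first_fitbit_date: dt.date

    def __post_init__(self) -> None:
        if self.pregnancy_start_date >= self.delivery_date:
            raise PhenotypingError(
                f"person {self.person_id}: pregnancy_start_date "
                f"{self.pregnancy_start_date} must precede delivery_date "
                f"{self.delivery_date}"
            )
        if self.age_at_index <= 0:
            raise PhenotypingError(
                f"person {self.person_id}: age_at_index must be positive"
            )


@dataclass(frozen=True)
class EHREvent:
    """A dated clinical event with a class label."""

    person_id: str
    event_date: dt.date
    event_class: EventClass


@dataclass(frozen=True)
class CohortAssignment:
    person_id: str
    cohort: Cohort
    index_date: dt.date
    days_delivery_to_index: int


@dataclass(frozen=True)
class PeriodAssignment:
    """A closed calendar interval [start_date, end_date] for one period.

    ``empty`` flags windows whose start falls after their end (e.g. a PPD
    diagnosis so early that no depression-free postpartum days exist); empty
    windows contribute no days to any denominator.
    """

    person_id: str
    period: Period
    start_date: dt.date
    end_date: dt.date
    empty: bool = False

    @property
    def n_days(self) -> int:
        if self.empty:
            return 0
        return (self.end_date - self.start_date).days + 1

    def contains(self, date: dt.date) -> bool:
        return (not self.empty) and self.start_date <= date <= self.end_date


def classify_ppd(
    events: Iterable[EHREvent],
    delivery_date: dt.date,
    window_months: int = 24,
) -> tuple[bool, dt.date | None]:
    """Apply the three-fold PPD rule to one woman's EHR events.

    An event qualifies when its class is a PPD diagnosis, a depression
    diagnosis, or antidepressant exposure, and it falls strictly after
    delivery but within ``window_months`` (24 months == 730 days) of it.
    Returns ``(is_ppd, index_date)`` where the index date is the earliest
    qualifying event date, or ``None`` when no event qualifies.
    """
    if delivery_date is None:
        ids = {e.person_id for e in events}
        who = ", ".join(sorted(ids)) or "<unknown>"
        raise PhenotypingError(f"person {who}: delivery_date is missing")
    window_days = round(window_months * 730 / 24)
    horizon = delivery_date + dt.timedelta(days=window_days)
    qualifying = [
        e.event_date
        for e in events
        if EventClass(e.event_class) in QUALIFYING_CLASSES
        and delivery_date < e.event_date <= horizon
    ]
    if not qualifying:
        return False, None
    return True, min(qualifying)


def ppd_equivalent_index(delivery_date: dt.date, offset_days: int = 58) -> dt.date:
    """Index date for the non-PPD pseudo window: delivery + offset.

    The default offset of 58 days is the PPD cohort's median
    delivery-to-diagnosis delay.
    """
    if offset_days < 0:
        raise ConfigurationError(
            f"ppd-equivalent offset must be non-negative, got {offset_days}"
        )
    return delivery_date + dt.timedelta(days=offset_days)


def assign_cohort(
    person: PersonRecord,
    events: Iterable[EHREvent],
    config: AnalysisConfig | None = None,
) -> CohortAssignment:
    """Classify one woman and locate her (real or equivalent) index date."""
    config = config or AnalysisConfig()
    is_ppd, index = classify_ppd(
        list(events), person.delivery_date, config.ppd_window_months
    )
    if is_ppd:
        assert index is not None
        cohort = Cohort.PPD
    else:
        cohort = Cohort.NON_PPD
        index = ppd_equivalent_index(
            person.delivery_date, config.ppd_equivalent_offset_days
        )
    return CohortAssignment(
        person_id=person.person_id,
        cohort=cohort,
        index_date=index,
        days_delivery_to_index=(index - person.delivery_date).days,
    )


def _window(
    person_id: str, period: Period, start: dt.date, end: dt.date
) -> PeriodAssignment:
    return PeriodAssignment(
        person_id=person_id,
        period=period,
        start_date=start,
        end_date=end,
        empty=start > end,
    )


def segment_periods(
    person: PersonRecord,
    assignment: CohortAssignment,
    config: AnalysisConfig | None = None,
) -> list[PeriodAssignment]:
    """Segment one woman's calendar into the four analysis periods.

    For the PPD cohort the postpartum period ends the day before the PPD
    window opens (index - 15 d), keeping the two disjoint even though the
    window reaches back before the diagnosis. For the non-PPD cohort the
    span [index - 14 d, index - 1 d] belongs to no period at all.
    """
    config = config or AnalysisConfig()
    index = assignment.index_date
    if assignment.cohort is Cohort.PPD and index <= person.delivery_date:
        raise PhenotypingError(
            f"person {person.person_id}: PPD index date {index} does not "
            f"fall after delivery {person.delivery_date}"
        )
    day = dt.timedelta(days=1)
    if assignment.cohort is Cohort.PPD:
        ppd_start = index - dt.timedelta(days=config.ppd_pre_days)
    else:
        ppd_start = index
    pre = _window(
        person.person_id,
        Period.PRE_PREGNANCY,
        index - dt.timedelta(days=config.prepregnancy_lookback_days),
        person.pregnancy_start_date - day,
    )
    # The PPD window takes precedence over every earlier period: a
    # diagnosis within a fortnight of delivery pulls the window's start
    # back across the delivery date, so pregnancy is clipped the same way
    # postpartum is.
    pregnancy = _window(
        person.person_id,
        Period.PREGNANCY,
        person.pregnancy_start_date,
        min(person.delivery_date, ppd_start - day),
    )
    postpartum = _window(
        person.person_id,
        Period.POSTPARTUM,
        person.delivery_date + day,
        index - dt.timedelta(days=config.ppd_pre_days + 1),
    )
    ppd = _window(
        person.person_id,
        Period.PPD_WINDOW,
        ppd_start,
        index + dt.timedelta(days=config.ppd_post_days),
    )
    return [pre, pregnancy, postpartum, ppd]


def filter_eligible(
    persons: Sequence[PersonRecord],
    daily_records: pd.DataFrame,
    periods: Mapping[str, Sequence[PeriodAssignment]],
) -> set[str]:
    """Persons with at least one device-data day inside any of their periods.

    A record counts only if its date is on/after the person's first device
    date (before that the woman may simply not have owned a device).
    ``daily_records`` needs columns ``person_id`` and ``date``.
    """
    if daily_records.empty:
        return set()
    dates_by_person: dict[str, set[dt.date]] = {
        pid: set(grp["date"]) for pid, grp in daily_records.groupby("person_id")
    }
    eligible: set[str] = set()
    for person in persons:
        dates = dates_by_person.get(person.person_id, ())
        for date in dates:
            if date < person.first_fitbit_date:
                continue
            if any(p.contains(date) for p in periods.get(person.person_id, ())):
                eligible.add(person.person_id)
                break
    return eligible
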