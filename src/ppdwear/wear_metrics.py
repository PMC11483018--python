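"""Wear-time digital biomarkers from step and sleep streams.

Wear time is inferred from the presence of step data: an hour with at least
one recorded step is a wear hour, and a day with at least one wear hour is
a worn day. Sleep wear is a separate per-date binary — any "main sleep"
record for that date. Per-period summaries divide worn-day counts by the
full calendar span of the period (clipped to start no earlier than the
person's first day of any device data), so days without records count as
not worn rather than being dropped.

The literature's "valid day" rule (>=10 wear hours and 100–45000 steps) is
computed as a diagnostic flag only; it is never used to filter days,
because the object of study is wear behaviour itself, including sparse
wear.
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass
from typing import Iterable

import numpy as np
import pandas as pd

from .phenotyping import PeriodAssignment, Period

__all__ = [
    "WearInputError",
    "PersonPeriodSummary",
    "derive_daily_wear",
    "attach_sleep",
    "valid_day_flags",
    "max_consecutive_worn",
    "summarize_period",
    "summarize_all",
]

VALID_DAY_MIN_HOURS = 10
VALID_DAY_MIN_STEPS = 100
VALID_DAY_MAX_STEPS = 45_000

DAILY_COLUMNS = [
    "person_id", "date", "hours_worn", "steps_total",
    "worn", "sleep_worn", "valid_day",
]


class WearInputError(ValueError):
    """Raised on malformed step or sleep input rows."""


@dataclass(frozen=True)
class PersonPeriodSummary:
    """Wear-time summary of one person in one analysis period.

    ``empty`` marks summaries whose window vanished — either the period
    itself was empty or it ended before the person owned a device; such
    rows carry no denominators and are excluded from all models.
    ``mean_hours_on_worn_days`` is NaN when no day was worn.
    """

    person_id: str
    period: Period
    n_days_total: int
    n_days_with_data: int
    n_days_worn: int
    pct_worn: float
    n_days_sleep_worn: int
    pct_sleep_worn: float
    max_consecutive_worn: int
    mean_hours_on_worn_days: float
    empty: bool = False

    @classmethod
    def empty_summary(cls, person_id: str, period: Period) -> "PersonPeriodSummary":
        return cls(
            person_id=person_id, period=period, n_days_total=0,
            n_days_with_data=0, n_days_worn=0,
            pct_worn=float("nan"), n_days_sleep_worn=0,
            pct_sleep_worn=float("nan"), max_consecutive_worn=0,
            mean_hours_on_worn_days=float("nan"), empty=True,
        )


def _validate_hourly(hourly: pd.DataFrame) -> None:
    required = {"person_id", "date", "hour", "steps"}
    missing = required - set(hourly.columns)
    if missing:
        raise WearInputError(f"hourly step table missing columns {sorted(missing)}")
    bad_hour = ~hourly["hour"].between(0, 23)
    if bad_hour.any():
        row = int(np.flatnonzero(bad_hour.to_numpy())[0])
        raise WearInputError(
            f"hour outside 0–23 at row {row} "
            f"(value {hourly['hour'].iloc[row]})"
        )
    bad_steps = hourly["steps"] < 0
    if bad_steps.any():
        row = int(np.flatnonzero(bad_steps.to_numpy())[0])
        raise WearInputError(
            f"negative step count at row {row} "
            f"(value {hourly['steps'].iloc[row]})"
        )
    dup = hourly.duplicated(subset=["person_id", "date", "hour"])
    if dup.any():
        row = int(np.flatnonzero(dup.to_numpy())[0])
        raise WearInputError(f"duplicate (person, date, hour) at row {row}")


def derive_daily_wear(
    hourly: pd.DataFrame,
    wear_hour_min_steps: int = 1,
    worn_day_min_hours: int = 1,
) -> pd.DataFrame:
    """Collapse hourly step records into per-day wear records.

    Per (person, date): ``hours_worn`` counts hours with at least
    ``wear_hour_min_steps`` steps, ``steps_total`` sums all steps, and
    ``worn`` is true when ``hours_worn >= worn_day_min_hours``. Dates with
    no hourly record at all produce no row — absent days are handled by the
    period summaries, where they count as not worn.
    """
    if hourly.empty:
        return pd.DataFrame(columns=DAILY_COLUMNS)
    _validate_hourly(hourly)
    grouped = (
        hourly.assign(_wear=(hourly["steps"] >= wear_hour_min_steps))
        .groupby(["person_id", "date"], sort=True)
        .agg(hours_worn=("_wear", "sum"), steps_total=("steps", "sum"))
        .reset_index()
    )
    grouped["hours_worn"] = grouped["hours_worn"].astype(int)
    grouped["worn"] = grouped["hours_worn"] >= worn_day_min_hours
    grouped["sleep_worn"] = False
    grouped["valid_day"] = valid_day_flags(grouped)
    return grouped[DAILY_COLUMNS]


def valid_day_flags(daily: pd.DataFrame) -> pd.Series:
    """Diagnostic 'valid day' flag: >=10 wear hours and 100–45000 steps."""
    return (
        (daily["hours_worn"] >= VALID_DAY_MIN_HOURS)
        & daily["steps_total"].between(VALID_DAY_MIN_STEPS, VALID_DAY_MAX_STEPS)
    )


def attach_sleep(daily: pd.DataFrame, sleep: pd.DataFrame) -> pd.DataFrame:
    """Mark sleep-worn dates from main-sleep records.

    A date with a main-sleep record but no step data still yields a daily
    row (hours_worn 0, worn False, sleep_worn True): the two binaries are
    independent definitions.
    """
    if sleep.empty:
        return daily.copy()
    required = {"person_id", "date", "is_main_sleep"}
    missing = required - set(sleep.columns)
    if missing:
        raise WearInputError(f"sleep table missing columns {sorted(missing)}")
    dup = sleep.duplicated(subset=["person_id", "date"])
    if dup.any():
        row = int(np.flatnonzero(dup.to_numpy())[0])
        raise WearInputError(f"duplicate (person, date) sleep record at row {row}")
    sleep_dates = sleep.loc[
        sleep["is_main_sleep"].astype(bool), ["person_id", "date"]
    ]
    merged = daily.drop(columns=["sleep_worn"]).merge(
        sleep_dates.assign(sleep_worn=True),
        on=["person_id", "date"],
        how="outer",
    )
    for col in ("sleep_worn", "worn", "valid_day"):
        merged[col] = merged[col].eq(True)
    for col in ("hours_worn", "steps_total"):
        merged[col] = merged[col].fillna(0).astype(int)
    return (
        merged[DAILY_COLUMNS]
        .sort_values(["person_id", "date"], kind="stable")
        .reset_index(drop=True)
    )


def max_consecutive_worn(
    dates_worn: Iterable[dt.date],
    window: tuple[dt.date, dt.date],
) -> int:
    """Longest run of consecutive worn calendar days inside a window."""
    start, end = window
    days = sorted(d for d in set(dates_worn) if start <= d <= end)
    best = run = 0
    prev: dt.date | None = None
    for d in days:
        run = run + 1 if prev is not None and (d - prev).days == 1 else 1
        best = max(best, run)
        prev = d
    return best


def summarize_period(
    person_id: str,
    period: PeriodAssignment,
    daily: pd.DataFrame,
    first_fitbit_date: dt.date,
) -> PersonPeriodSummary:
    """Summarize one person's wear behaviour over one period.

    The window is clipped to start no earlier than ``first_fitbit_date``
    (nobody is labelled non-adherent before owning a device); every
    calendar day of the clipped window enters the denominator, recorded or
    not.
    """
    if period.empty:
        return PersonPeriodSummary.empty_summary(person_id, period.period)
    start = max(period.start_date, first_fitbit_date)
    end = period.end_date
    if start > end:
        return PersonPeriodSummary.empty_summary(person_id, period.period)
    n_total = (end - start).days + 1
    mask = (daily["person_id"] == person_id) & (daily["date"] >= start) & (
        daily["date"] <= end
    )
    in_window = daily.loc[mask]
    worn_dates = set(in_window.loc[in_window["worn"].astype(bool), "date"])
    n_worn = len(worn_dates)
    n_sleep = int(in_window["sleep_worn"].astype(bool).sum())
    if n_worn:
        mean_hours = float(
            in_window.loc[in_window["worn"].astype(bool), "hours_worn"].mean()
        )
    else:
        mean_hours = float("nan")
    return PersonPeriodSummary(
        person_id=person_id,
        period=period.period,
        n_days_total=n_total,
        n_days_with_data=int(len(in_window)),
        n_days_worn=n_worn,
        pct_worn=100.0 * n_worn / n_total,
        n_days_sleep_worn=n_sleep,
        pct_sleep_worn=100.0 * n_sleep / n_total,
        max_consecutive_worn=max_consecutive_worn(worn_dates, (start, end)),
        mean_hours_on_worn_days=mean_hours,
    )


def summarize_all(
    periods_by_person: dict[str, list[PeriodAssignment]],
    daily: pd.DataFrame,
    first_fitbit_dates: dict[str, dt.date],
) -> pd.DataFrame:
    """One row per person x period with every summary field."""
    rows = []
    for pid, periods in periods_by_person.items():
        person_daily = daily.loc[daily["person_id"] == pid]
        for period in periods:
            s = summarize_period(pid, period, person_daily, first_fitbit_dates[pid])
            rows.append(
                {
                    "person_id": s.person_id,
                    "period": s.period.value,
                    "n_days_total": s.n_days_total,
                    "n_days_with_data": s.n_days_with_data,
                    "n_days_worn": s.n_days_worn,
                    "pct_worn": s.pct_worn,
                    "n_days_sleep_worn": s.n_days_sleep_worn,
                    "pct_sleep_worn": s.pct_sleep_worn,
                    "max_consecutive_worn": s.max_consecutive_worn,
                    "mean_hours_on_worn_days": s.mean_hours_on_worn_days,
                    "empty": s.empty,
                }
            )
    return pd.DataFrame(rows)
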