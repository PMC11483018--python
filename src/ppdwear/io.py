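"""CSV readers/writers for the four long-format input tables.

persons.csv: person_id, age_at_index, race_ethnicity,
    pregnancy_start_date, delivery_date, first_fitbit_date (ISO-8601)
events.csv: person_id, event_date, event_class
steps_hourly.csv: person_id, date, hour, steps
sleep_daily.csv: person_id, date, is_main_sleep

Dates are whole calendar days (no time zones); schema violations raise
:class:`SchemaError` naming the file, column and first offending row.
"""

from __future__ import annotations

import datetime as dt
from pathlib import Path

import numpy as np
import pandas as pd

from .phenotyping import EHREvent, EventClass, PersonRecord

__all__ = [
    "SchemaError",
    "read_persons",
    "read_events",
    "read_steps_hourly",
    "read_sleep_daily",
]


class SchemaError(ValueError):
    """Raised when an input file violates its expected schema."""


def _require_columns(df: pd.DataFrame, columns: list[str], path: Path) -> None:
    missing = [c for c in columns if c not in df.columns]
    if missing:
        raise SchemaError(f"{path.name}: missing columns {missing}")


def _parse_dates(df: pd.DataFrame, column: str, path: Path) -> pd.Series:
    parsed = pd.to_datetime(df[column], format="ISO8601", errors="coerce")
    bad = parsed.isna() & df[column].notna()
    if df[column].isna().any():
        row = int(np.flatnonzero(df[column].isna().to_numpy())[0])
        raise SchemaError(f"{path.name}: empty {column} at row {row + 2}")
    if bad.any():
        row = int(np.flatnonzero(bad.to_numpy())[0])
        raise SchemaError(
            f"{path.name}: malformed {column} at row {row + 2} "
            f"(value {df[column].iloc[row]!r})"
        )
    return parsed.dt.date


def read_persons(path: str | Path) -> list[PersonRecord]:
    path = Path(path)
    df = pd.read_csv(path)
    _require_columns(
        df,
        ["person_id", "age_at_index", "race_ethnicity",
         "pregnancy_start_date", "delivery_date", "first_fitbit_date"],
        path,
    )
    for col in ("pregnancy_start_date", "delivery_date", "first_fitbit_date"):
        df[col] = _parse_dates(df, col, path)
    return [
        PersonRecord(
            person_id=str(r.person_id),
            age_at_index=float(r.age_at_index),
            race_ethnicity=str(r.race_ethnicity),
            pregnancy_start_date=r.pregnancy_start_date,
            delivery_date=r.delivery_date,
            first_fitbit_date=r.first_fitbit_date,
        )
        for r in df.itertuples(index=False)
    ]


def read_events(path: str | Path) -> list[EHREvent]:
    path = Path(path)
    df = pd.read_csv(path)
    _require_columns(df, ["person_id", "event_date", "event_class"], path)
    df["event_date"] = _parse_dates(df, "event_date", path)
    valid = {e.value for e in EventClass}
    bad = ~df["event_class"].isin(valid)
    if bad.any():
        row = int(np.flatnonzero(bad.to_numpy())[0])
        raise SchemaError(
            f"{path.name}: unknown event_class at row {row + 2} "
            f"(value {df['event_class'].iloc[row]!r}; expected one of "
            f"{sorted(valid)})"
        )
    return [
        EHREvent(
            person_id=str(r.person_id),
            event_date=r.event_date,
            event_class=EventClass(r.event_class),
        )
        for r in df.itertuples(index=False)
    ]


def read_steps_hourly(path: str | Path) -> pd.DataFrame:
    path = Path(path)
    df = pd.read_csv(path)
    _require_columns(df, ["person_id", "date", "hour", "steps"], path)
    df["person_id"] = df["person_id"].astype(str)
    df["date"] = _parse_dates(df, "date", path)
    for col in ("hour", "steps"):
        if not pd.api.types.is_numeric_dtype(df[col]):
            raise SchemaError(f"{path.name}: column {col} must be numeric")
    return df


def read_sleep_daily(path: str | Path) -> pd.DataFrame:
    path = Path(path)
    df = pd.read_csv(path)
    _require_columns(df, ["person_id", "date", "is_main_sleep"], path)
    df["person_id"] = df["person_id"].astype(str)
    df["date"] = _parse_dates(df, "date", path)
    return df
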