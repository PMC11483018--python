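"""Synthetic cohorts with the statistical structure the analysis assumes.

The generator emulates the bring-your-own-device layout of a research
wearable dataset: per-woman EHR anchor events (pregnancy start, delivery,
a qualifying depression event for the PPD cohort), hourly step streams and
daily main-sleep records. Default parameters are calibrated to the
published cohort: 41 PPD / 101 non-PPD women, worn-day probabilities per
cohort and pregnancy phase equal to the reported adjusted means (e.g.
70.7% vs 55.6% in the PPD window, 72.9% vs 58.9% postpartum), daily hours
on worn days around 14–18 h, sleep-wear probabilities matching the
reported sleep-wear percentages, and a log-normal delivery-to-diagnosis
delay with median 58 days capped at the 24-month horizon.

Wear behaviour is simulated as a two-state Markov chain over calendar
days whose stationary marginal equals the configured worn-day
probability; ``wear_persistence`` is the probability of copying the
previous day's state (0 reduces to i.i.d. Bernoulli days). A person-level
latent propensity on the logit scale (``propensity_sd``) is shared across
periods and induces the positive cross-period wear correlation seen in
real adherence data.
"""

from __future__ import annotations

import dataclasses
import datetime as dt
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .config import AnalysisConfig, ConfigurationError
from .phenotyping import (
    Cohort,
    CohortAssignment,
    EventClass,
    Period,
    PersonRecord,
    ppd_equivalent_index,
    segment_periods,
)

__all__ = [
    "SyntheticConfig",
    "SyntheticCohort",
    "calibrated_preset",
    "generate_cohort",
    "simulate_window_cohort",
    "sample_onset_days",
    "bivariate_percent_pairs",
]

RACE_MAJORITY = "White non-Hispanic"
RACE_OTHER = "Another race or ethnicity"

_PPD = Cohort.PPD.value
_NON = Cohort.NON_PPD.value
_PRE = Period.PRE_PREGNANCY.value
_PREG = Period.PREGNANCY.value
_POST = Period.POSTPARTUM.value
_PPDW = Period.PPD_WINDOW.value


def _preset_wear() -> dict[str, dict[str, float]]:
    # Postpartum and PPD-window cells are the published adjusted means;
    # pre-pregnancy and pregnancy were reported only as "no difference",
    # so both cohorts share mid-range values there.
    return {
        _PPD: {_PRE: 0.57, _PREG: 0.63, _POST: 0.729, _PPDW: 0.707},
        _NON: {_PRE: 0.57, _PREG: 0.63, _POST: 0.589, _PPDW: 0.556},
    }


def _preset_hours() -> dict[str, dict[str, float]]:
    return {
        _PPD: {_PRE: 14.4, _PREG: 15.8, _POST: 16.5, _PPDW: 17.4},
        _NON: {_PRE: 14.8, _PREG: 16.4, _POST: 17.2, _PPDW: 17.8},
    }


def _preset_sleep_unconditional() -> dict[str, dict[str, float]]:
    return {
        _PPD: {_PRE: 0.45, _PREG: 0.50, _POST: 0.589, _PPDW: 0.644},
        _NON: {_PRE: 0.45, _PREG: 0.50, _POST: 0.456, _PPDW: 0.498},
    }


def _preset_sleep_given_worn() -> dict[str, dict[str, float]]:
    wear = _preset_wear()
    target = _preset_sleep_unconditional()
    return {
        c: {p: target[c][p] / wear[c][p] for p in target[c]} for c in target
    }


@dataclass
class SyntheticConfig:
    """Generator parameters; the defaults are the calibrated study preset.

    ``wear_prob[cohort][period]`` is the marginal worn-day probability;
    ``sleep_given_worn``/``sleep_given_not_worn`` couple sleep wear to day
    wear so that the unconditional sleep-wear probability equals
    ``wear_prob * sleep_given_worn + (1 - wear_prob) * sleep_given_not_worn``.
    Hours on worn days follow a rounded truncated normal on [1, 24] with a
    person-level mean shift of SD ``hours_between_sd``. The PPD onset delay
    is log-normal parameterized by its median, resampled above the
    ``onset_cap_days`` horizon.
    """

    n_ppd: int = 41
    n_nonppd: int = 101
    seed: int = 0
    wear_prob: dict[str, dict[str, float]] = field(default_factory=_preset_wear)
    wear_persistence: float = 0.3
    hours_mean: dict[str, dict[str, float]] = field(default_factory=_preset_hours)
    hours_sd: float = 2.0
    hours_between_sd: float = 1.5
    sleep_given_worn: dict[str, dict[str, float]] = field(
        default_factory=_preset_sleep_given_worn
    )
    sleep_given_not_worn: float = 0.0
    onset_log_median: float = 58.0
    onset_log_sigma: float = 0.7
    onset_cap_days: int = 730
    propensity_sd: float = 0.6
    age_mean: float = 33.0
    age_sd: float = 4.0
    race_majority_prob: dict[str, float] = field(
        default_factory=lambda: {_PPD: 0.878, _NON: 0.752}
    )
    gestation_days: int = 280
    ownership_lag_days: tuple[int, int] = (0, 60)
    delivery_span: tuple[dt.date, dt.date] = (
        dt.date(2018, 7, 1),
        dt.date(2020, 6, 30),
    )
    nonppd_decoy_rate: float = 0.1
    steps_per_hour_max: int = 600

    def __post_init__(self) -> None:
        if self.n_ppd + self.n_nonppd < 2:
            raise ConfigurationError("need at least 2 persons in total")
        for table in (self.wear_prob, self.sleep_given_worn):
            for by_period in table.values():
                for p in by_period.values():
                    if not 0.0 <= p <= 1.0:
                        raise ConfigurationError(
                            f"probability {p} outside [0, 1]"
                        )
        for p in (self.wear_persistence, self.sleep_given_not_worn,
                  self.nonppd_decoy_rate):
            if not 0.0 <= p <= 1.0:
                raise ConfigurationError(f"probability {p} outside [0, 1]")
        if self.hours_sd <= 0 or self.hours_between_sd < 0:
            raise ConfigurationError("hours SDs must be positive")
        for by_period in self.hours_mean.values():
            for mu in by_period.values():
                if mu > 24 + 4 * self.hours_sd or mu < 1 - 4 * self.hours_sd:
                    raise ConfigurationError(
                        f"hours mean {mu} makes the [1, 24] truncation "
                        "effectively impossible"
                    )
        if self.onset_log_median <= 0 or self.onset_log_sigma < 0:
            raise ConfigurationError("onset distribution parameters invalid")

    def sleep_prob(self, cohort: str, period: str) -> float:
        """Unconditional daily sleep-wear probability for a cohort/period."""
        p = self.wear_prob[cohort][period]
        return (
            p * self.sleep_given_worn[cohort][period]
            + (1.0 - p) * self.sleep_given_not_worn
        )


def calibrated_preset() -> SyntheticConfig:
    """The calibrated study preset (identical to the defaults)."""
    return SyntheticConfig()


@dataclass
class SyntheticCohort:
    """Generated tables plus the ground truth behind them."""

    persons: pd.DataFrame
    events: pd.DataFrame
    steps_hourly: pd.DataFrame
    sleep_daily: pd.DataFrame
    truth: dict

    def write(self, out_dir: str | Path) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        self.persons.to_csv(out / "persons.csv", index=False)
        self.events.to_csv(out / "events.csv", index=False)
        self.steps_hourly.to_csv(out / "steps_hourly.csv", index=False)
        self.sleep_daily.to_csv(out / "sleep_daily.csv", index=False)
        (out / "truth.json").write_text(json.dumps(self.truth, indent=2))


def _logit(p: float) -> float:
    return float(np.log(p) - np.log1p(-p))


def _expit(x: float) -> float:
    return float(1.0 / (1.0 + np.exp(-x)))


def _markov_days(
    rng: np.random.Generator, n_days: int, p: float, persistence: float
) -> np.ndarray:
    """Worn/not-worn day chain with stationary marginal p."""
    if p <= 0.0:
        return np.zeros(n_days, bool)
    if p >= 1.0:
        return np.ones(n_days, bool)
    draws = rng.random(n_days) < p
    if persistence == 0.0 or n_days == 0:
        return draws
    copy_prev = rng.random(n_days) < persistence
    worn = np.empty(n_days, bool)
    worn[0] = draws[0]
    for i in range(1, n_days):
        worn[i] = worn[i - 1] if copy_prev[i] else draws[i]
    return worn


def sample_onset_days(
    n: int, config: SyntheticConfig, rng: np.random.Generator
) -> np.ndarray:
    """Delivery-to-diagnosis delays: rounded log-normal, median 58 d.

    Draws above the cap (24-month horizon) are resampled; results are
    whole days of at least 1.
    """
    mu = np.log(config.onset_log_median)
    out = np.empty(n, float)
    remaining = np.arange(n)
    while remaining.size:
        draw = rng.lognormal(mu, config.onset_log_sigma, remaining.size)
        ok = draw <= config.onset_cap_days
        out[remaining[ok]] = draw[ok]
        remaining = remaining[~ok]
    return np.maximum(np.rint(out).astype(int), 1)


def _simulate_person_days(
    rng: np.random.Generator,
    person_id: str,
    dates: Sequence[dt.date],
    p_worn: float,
    hours_mu: float,
    config: SyntheticConfig,
    sleep_given_worn: float,
    persistence: float,
    step_rows: list,
    sleep_rows: list,
) -> None:
    """Simulate one person's hourly steps and sleep flags over dates."""
    n = len(dates)
    if n == 0:
        return
    worn = _markov_days(rng, n, p_worn, persistence)
    worn_dates = [d for d, w in zip(dates, worn) if w]
    k = len(worn_dates)
    if k:
        lo, hi = (1.0 - hours_mu) / config.hours_sd, (24.0 - hours_mu) / config.hours_sd
        raw = sps.truncnorm.rvs(lo, hi, loc=hours_mu, scale=config.hours_sd,
                                size=k, random_state=rng)
        n_hours = np.clip(np.rint(raw).astype(int), 1, 24)
        # distinct clock hours per worn day, each with at least one step
        order = np.argsort(rng.random((k, 24)), axis=1)
        mask = np.arange(24)[None, :] < n_hours[:, None]
        hours_flat = order[mask]
        dates_flat = np.repeat(np.asarray(worn_dates, object), n_hours)
        steps_flat = rng.integers(1, config.steps_per_hour_max + 1,
                                  size=hours_flat.size)
        step_rows.append(
            pd.DataFrame(
                {
                    "person_id": person_id,
                    "date": dates_flat,
                    "hour": hours_flat,
                    "steps": steps_flat,
                }
            )
        )
    p_sleep = np.where(worn, sleep_given_worn, config.sleep_given_not_worn)
    sleep = rng.random(n) < p_sleep
    sleep_dates = [d for d, s in zip(dates, sleep) if s]
    if sleep_dates:
        sleep_rows.append(
            pd.DataFrame(
                {
                    "person_id": person_id,
                    "date": sleep_dates,
                    "is_main_sleep": True,
                }
            )
        )


def _date_range(start: dt.date, end: dt.date) -> list[dt.date]:
    return [start + dt.timedelta(days=i) for i in range((end - start).days + 1)]


def generate_cohort(
    config: SyntheticConfig | None = None,
    seed: int | None = None,
    analysis_config: AnalysisConfig | None = None,
) -> SyntheticCohort:
    """Generate a full synthetic cohort (persons, events, steps, sleep).

    Every woman's intended cohort round-trips through the phenotyping
    rules: PPD women get exactly one qualifying event at delivery + onset
    (onset capped inside the 24-month window), non-PPD women get none
    (a fraction receive a depression diagnosis beyond the window, which
    must not qualify). Fully deterministic given the seed.
    """
    config = config or SyntheticConfig()
    analysis_config = analysis_config or AnalysisConfig()
    rng = np.random.default_rng(config.seed if seed is None else seed)
    span_days = (config.delivery_span[1] - config.delivery_span[0]).days

    person_rows, event_rows, truth_people = [], [], []
    step_rows: list[pd.DataFrame] = []
    sleep_rows: list[pd.DataFrame] = []
    cohorts = [_PPD] * config.n_ppd + [_NON] * config.n_nonppd
    onsets = sample_onset_days(config.n_ppd, config, rng)

    qualifying = [
        EventClass.PPD_DIAGNOSIS,
        EventClass.DEPRESSION_DIAGNOSIS,
        EventClass.ANTIDEPRESSANT_EXPOSURE,
    ]
    ppd_i = 0
    for i, cohort in enumerate(cohorts):
        pid = f"P{i:04d}"
        delivery = config.delivery_span[0] + dt.timedelta(
            days=int(rng.integers(0, span_days + 1))
        )
        pregnancy_start = delivery - dt.timedelta(days=config.gestation_days)
        if cohort == _PPD:
            onset = int(onsets[ppd_i])
            ppd_i += 1
            index = delivery + dt.timedelta(days=onset)
            event_rows.append(
                (pid, index, qualifying[int(rng.integers(0, 3))].value)
            )
        else:
            index = ppd_equivalent_index(
                delivery, analysis_config.ppd_equivalent_offset_days
            )
            if rng.random() < config.nonppd_decoy_rate:
                # depression diagnosis beyond the 24-month horizon: must
                # not pull this woman into the PPD cohort
                event_rows.append(
                    (
                        pid,
                        delivery + dt.timedelta(days=800),
                        EventClass.DEPRESSION_DIAGNOSIS.value,
                    )
                )
        event_rows.append((pid, delivery, EventClass.DELIVERY.value))
        event_rows.append((pid, pregnancy_start, EventClass.PREGNANCY_START.value))

        age = float(np.clip(rng.normal(config.age_mean, config.age_sd), 18, 45))
        race = (
            RACE_MAJORITY
            if rng.random() < config.race_majority_prob[cohort]
            else RACE_OTHER
        )
        pre_start = index - dt.timedelta(
            days=analysis_config.prepregnancy_lookback_days
        )
        lag = int(rng.integers(config.ownership_lag_days[0],
                               config.ownership_lag_days[1] + 1))
        first_fitbit = pre_start - dt.timedelta(days=lag)
        person = PersonRecord(
            person_id=pid,
            age_at_index=round(age, 1),
            race_ethnicity=race,
            pregnancy_start_date=pregnancy_start,
            delivery_date=delivery,
            first_fitbit_date=first_fitbit,
        )
        person_rows.append(person)
        truth_people.append(
            {
                "person_id": pid,
                "cohort": cohort,
                "index_date": index.isoformat(),
                "days_delivery_to_index": (index - delivery).days,
            }
        )

        assignment = CohortAssignment(
            person_id=pid,
            cohort=Cohort(cohort),
            index_date=index,
            days_delivery_to_index=(index - delivery).days,
        )
        periods = segment_periods(person, assignment, analysis_config)
        b = rng.normal(0.0, config.propensity_sd) if config.propensity_sd else 0.0
        hours_shift = (
            rng.normal(0.0, config.hours_between_sd)
            if config.hours_between_sd
            else 0.0
        )
        for period in periods:
            if period.empty:
                continue
            p0 = config.wear_prob[cohort][period.period.value]
            if 0.0 < p0 < 1.0:
                p_eff = _expit(_logit(p0) + b)
            else:
                p_eff = p0
            _simulate_person_days(
                rng,
                pid,
                _date_range(period.start_date, period.end_date),
                p_eff,
                config.hours_mean[cohort][period.period.value] + hours_shift,
                config,
                config.sleep_given_worn[cohort][period.period.value],
                config.wear_persistence,
                step_rows,
                sleep_rows,
            )

    persons = pd.DataFrame(
        {
            "person_id": [p.person_id for p in person_rows],
            "age_at_index": [p.age_at_index for p in person_rows],
            "race_ethnicity": [p.race_ethnicity for p in person_rows],
            "pregnancy_start_date": [p.pregnancy_start_date for p in person_rows],
            "delivery_date": [p.delivery_date for p in person_rows],
            "first_fitbit_date": [p.first_fitbit_date for p in person_rows],
        }
    )
    events = pd.DataFrame(
        event_rows, columns=["person_id", "event_date", "event_class"]
    ).sort_values(["person_id", "event_date"], kind="stable").reset_index(drop=True)
    steps = (
        pd.concat(step_rows, ignore_index=True)
        if step_rows
        else pd.DataFrame(columns=["person_id", "date", "hour", "steps"])
    )
    if not steps.empty:
        steps = steps.sort_values(
            ["person_id", "date", "hour"], kind="stable"
        ).reset_index(drop=True)
    sleep = (
        pd.concat(sleep_rows, ignore_index=True)
        if sleep_rows
        else pd.DataFrame(columns=["person_id", "date", "is_main_sleep"])
    )
    truth = {
        "config": _config_as_json(config),
        "n_ppd": config.n_ppd,
        "n_nonppd": config.n_nonppd,
        "persons": truth_people,
    }
    return SyntheticCohort(
        persons=persons,
        events=events,
        steps_hourly=steps,
        sleep_daily=sleep,
        truth=truth,
    )


def _config_as_json(config: SyntheticConfig) -> dict:
    raw = dataclasses.asdict(config)
    raw["delivery_span"] = [d.isoformat() for d in config.delivery_span]
    raw["ownership_lag_days"] = list(config.ownership_lag_days)
    return raw


def simulate_window_cohort(
    n_persons: int,
    cohort: str,
    period: str,
    n_days: int,
    config: SyntheticConfig | None = None,
    seed: int | None = None,
    start_date: dt.date = dt.date(2020, 1, 1),
) -> dict:
    """Simulate one cohort's wear data over a single fixed-length window.

    A lightweight front end to the same day/hour machinery used by
    :func:`generate_cohort`, for studies of one cohort x period cell
    (e.g. parameter-recovery runs): every person gets the same
    ``n_days``-day window, demographics drawn as usual, wear behaviour
    from the configured cell. Returns persons, hourly steps, sleep rows
    and the window bounds.
    """
    config = config or SyntheticConfig()
    rng = np.random.default_rng(config.seed if seed is None else seed)
    dates = _date_range(start_date, start_date + dt.timedelta(days=n_days - 1))
    p0 = config.wear_prob[cohort][period]
    step_rows: list[pd.DataFrame] = []
    sleep_rows: list[pd.DataFrame] = []
    people = []
    for i in range(n_persons):
        pid = f"W{i:04d}"
        age = float(np.clip(rng.normal(config.age_mean, config.age_sd), 18, 45))
        race = (
            RACE_MAJORITY
            if rng.random() < config.race_majority_prob[cohort]
            else RACE_OTHER
        )
        b = rng.normal(0.0, config.propensity_sd) if config.propensity_sd else 0.0
        hours_shift = (
            rng.normal(0.0, config.hours_between_sd)
            if config.hours_between_sd
            else 0.0
        )
        p_eff = _expit(_logit(p0) + b) if 0.0 < p0 < 1.0 else p0
        _simulate_person_days(
            rng,
            pid,
            dates,
            p_eff,
            config.hours_mean[cohort][period] + hours_shift,
            config,
            config.sleep_given_worn[cohort][period],
            config.wear_persistence,
            step_rows,
            sleep_rows,
        )
        people.append((pid, round(age, 1), race, cohort))
    persons = pd.DataFrame(
        people, columns=["person_id", "age", "race", "cohort"]
    )
    steps = (
        pd.concat(step_rows, ignore_index=True)
        if step_rows
        else pd.DataFrame(columns=["person_id", "date", "hour", "steps"])
    )
    sleep = (
        pd.concat(sleep_rows, ignore_index=True)
        if sleep_rows
        else pd.DataFrame(columns=["person_id", "date", "is_main_sleep"])
    )
    return {
        "persons": persons,
        "steps_hourly": steps,
        "sleep_daily": sleep,
        "window": (dates[0], dates[-1]),
    }


def bivariate_percent_pairs(
    n: int,
    rho: float,
    seed: int | None = None,
    mean: float = 60.0,
    sd: float = 15.0,
) -> tuple[np.ndarray, np.ndarray]:
    """Paired per-person percentages with target correlation ``rho``.

    Standard bivariate normal pairs with correlation rho, affinely mapped
    to mean/sd on the percent scale and clipped into [0, 100]; the
    empirical correlation approaches rho as n grows (clipping at ~2.7 SD
    attenuates it negligibly).
    """
    if not -1.0 <= rho <= 1.0:
        raise ConfigurationError(f"rho must be in [-1, 1], got {rho}")
    if n < 3:
        raise ConfigurationError(f"need n >= 3 pairs, got {n}")
    rng = np.random.default_rng(seed)
    z1 = rng.standard_normal(n)
    z2 = rng.standard_normal(n)
    x = z1
    y = rho * z1 + np.sqrt(max(0.0, 1.0 - rho * rho)) * z2
    to_pct = lambda z: np.clip(mean + sd * z, 0.0, 100.0)  # noqa: E731
    return to_pct(x), to_pct(y)
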