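"""End-to-end orchestration: phenotype -> wear metrics -> models -> report.

Consumes the four long-format CSVs (persons, EHR events, hourly steps,
daily sleep), classifies cohorts, segments timelines, derives wear
biomarkers, runs the per-period cohort comparisons and cross-period
correlations, and writes summaries.csv, comparison.csv, correlations.csv
and report.json. Every filtering step logs before/after person counts.
"""

from __future__ import annotations

import dataclasses
import datetime as dt
import json
import logging
from pathlib import Path

import pandas as pd

from .config import AnalysisConfig
from .io import read_events, read_persons, read_sleep_daily, read_steps_hourly
from .phenotyping import (
    Cohort,
    CohortAssignment,
    EHREvent,
    Period,
    PeriodAssignment,
    PersonRecord,
    assign_cohort,
    filter_eligible,
    segment_periods,
)
from .reporting import build_report
from .stats import (
    StatsError,
    compare_cohorts,
    compare_cohorts_hours,
    pearson,
)
from .wear_metrics import (
    attach_sleep,
    derive_daily_wear,
    summarize_all,
    summarize_period,
)

logger = logging.getLogger("ppdwear")

__all__ = [
    "PipelineInputs",
    "PhenotypeResult",
    "load_inputs",
    "phenotype_cohort",
    "compute_daily",
    "compute_summaries",
    "compute_comparisons",
    "compute_correlations",
    "run_pipeline",
    "summarize_window_simulation",
    "daily_hours_frame",
]

#: Cross-period correlation pairs examined for each cohort.
CORRELATION_PAIRS = (
    (Period.PRE_PREGNANCY, Period.PPD_WINDOW),
    (Period.PREGNANCY, Period.PPD_WINDOW),
)
CORRELATION_METRICS = ("pct_worn", "max_consecutive_worn")


@dataclasses.dataclass
class PipelineInputs:
    persons: list[PersonRecord]
    events: list[EHREvent]
    steps_hourly: pd.DataFrame
    sleep_daily: pd.DataFrame | None


@dataclasses.dataclass
class PhenotypeResult:
    assignments: dict[str, CohortAssignment]
    periods: dict[str, list[PeriodAssignment]]


def load_inputs(input_dir: str | Path) -> PipelineInputs:
    input_dir = Path(input_dir)
    persons = read_persons(input_dir / "persons.csv")
    events = read_events(input_dir / "events.csv")
    steps = read_steps_hourly(input_dir / "steps_hourly.csv")
    sleep_path = input_dir / "sleep_daily.csv"
    if sleep_path.exists():
        sleep = read_sleep_daily(sleep_path)
    else:
        logger.warning(
            "sleep_daily.csv not found: sleep-wear metrics will be unavailable"
        )
        sleep = None
    logger.info(
        "loaded %d persons, %d events, %d hourly step rows",
        len(persons), len(events), len(steps),
    )
    return PipelineInputs(persons, events, steps, sleep)


def phenotype_cohort(
    inputs: PipelineInputs, config: AnalysisConfig
) -> PhenotypeResult:
    events_by_person: dict[str, list[EHREvent]] = {}
    for e in inputs.events:
        events_by_person.setdefault(e.person_id, []).append(e)
    assignments, periods = {}, {}
    for person in inputs.persons:
        a = assign_cohort(person, events_by_person.get(person.person_id, []), config)
        assignments[person.person_id] = a
        periods[person.person_id] = segment_periods(person, a, config)
    n_ppd = sum(a.cohort is Cohort.PPD for a in assignments.values())
    logger.info(
        "phenotyped %d persons: %d PPD, %d non-PPD",
        len(assignments), n_ppd, len(assignments) - n_ppd,
    )
    return PhenotypeResult(assignments, periods)


def compute_daily(
    inputs: PipelineInputs, config: AnalysisConfig
) -> pd.DataFrame:
    daily = derive_daily_wear(
        inputs.steps_hourly,
        wear_hour_min_steps=config.wear_hour_min_steps,
        worn_day_min_hours=config.worn_day_min_hours,
    )
    if inputs.sleep_daily is not None:
        daily = attach_sleep(daily, inputs.sleep_daily)
    return daily


def compute_summaries(
    inputs: PipelineInputs,
    phenotypes: PhenotypeResult,
    daily: pd.DataFrame,
) -> tuple[pd.DataFrame, list[PersonRecord]]:
    """Eligibility filter plus person x period summary table."""
    eligible = filter_eligible(inputs.persons, daily, phenotypes.periods)
    kept = [p for p in inputs.persons if p.person_id in eligible]
    logger.info(
        "eligibility filter (any device data inside any period): "
        "%d -> %d persons", len(inputs.persons), len(kept),
    )
    summaries = summarize_all(
        {p.person_id: phenotypes.periods[p.person_id] for p in kept},
        daily,
        {p.person_id: p.first_fitbit_date for p in kept},
    )
    return summaries, kept


def _person_frame(
    kept: list[PersonRecord], phenotypes: PhenotypeResult
) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "person_id": [p.person_id for p in kept],
            "cohort": [
                phenotypes.assignments[p.person_id].cohort.value for p in kept
            ],
            "age": [p.age_at_index for p in kept],
            "race": [p.race_ethnicity for p in kept],
        }
    )


def _daily_with_period(
    daily: pd.DataFrame,
    kept: list[PersonRecord],
    phenotypes: PhenotypeResult,
) -> pd.DataFrame:
    """Day-level rows annotated with the analysis period they fall in."""
    frames = []
    for person in kept:
        rows = daily.loc[
            (daily["person_id"] == person.person_id)
            & (daily["date"] >= person.first_fitbit_date)
        ]
        if rows.empty:
            continue
        period_of: dict[dt.date, str] = {}
        for pa in phenotypes.periods[person.person_id]:
            if pa.empty:
                continue
            d = max(pa.start_date, person.first_fitbit_date)
            while d <= pa.end_date:
                period_of[d] = pa.period.value
                d += dt.timedelta(days=1)
        labeled = rows.assign(period=rows["date"].map(period_of))
        frames.append(labeled.dropna(subset=["period"]))
    if not frames:
        return daily.iloc[0:0].assign(period=pd.Series(dtype=object))
    return pd.concat(frames, ignore_index=True)


def compute_comparisons(
    summaries: pd.DataFrame,
    persons_df: pd.DataFrame,
    daily_periods: pd.DataFrame,
    config: AnalysisConfig,
    include_sleep: bool = True,
) -> pd.DataFrame:
    """Per-period cohort comparisons for wear %, sleep-wear % and hours."""
    data = summaries.merge(persons_df, on="person_id", how="inner")
    day_data = daily_periods.merge(persons_df, on="person_id", how="inner")
    rows = []
    metrics = ["pct_worn"] + (["pct_sleep_worn"] if include_sleep else [])
    for period in Period:
        for metric in metrics:
            try:
                r = compare_cohorts(data, metric, period.value, config)
            except StatsError as err:
                logger.warning(
                    "skipping %s/%s comparison: %s", period.value, metric, err
                )
                continue
            rows.append(dataclasses.asdict(r))
        try:
            r = compare_cohorts_hours(
                day_data.loc[day_data["period"] == period.value],
                period.value,
                config,
            )
        except StatsError as err:
            logger.warning(
                "skipping %s hours comparison: %s", period.value, err
            )
            continue
        rows.append(dataclasses.asdict(r))
    return pd.DataFrame(rows)


def compute_correlations(
    summaries: pd.DataFrame, persons_df: pd.DataFrame
) -> pd.DataFrame:
    """Cross-period wear and consistency correlations within each cohort."""
    data = summaries.merge(
        persons_df[["person_id", "cohort"]], on="person_id", how="inner"
    )
    rows = []
    for cohort in (Cohort.PPD.value, Cohort.NON_PPD.value):
        sub = data.loc[data["cohort"] == cohort]
        for metric in CORRELATION_METRICS:
            for earlier, later in CORRELATION_PAIRS:
                wide = (
                    sub.loc[~sub["empty"].astype(bool)]
                    .pivot_table(
                        index="person_id", columns="period", values=metric,
                        aggfunc="first",
                    )
                )
                if earlier.value not in wide or later.value not in wide:
                    continue
                try:
                    res = pearson(wide[earlier.value], wide[later.value])
                except StatsError as err:
                    logger.warning(
                        "skipping %s %s %s-%s correlation: %s",
                        cohort, metric, earlier.value, later.value, err,
                    )
                    continue
                rows.append(
                    {
                        "cohort": cohort,
                        "metric": metric,
                        "period_pair": f"{earlier.value}~{later.value}",
                        "r": res.r,
                        "p": res.p,
                        "n": res.n,
                    }
                )
    return pd.DataFrame(rows)


def summarize_window_simulation(sim: dict, period: Period) -> pd.DataFrame:
    """Per-person wear summaries for a single-window simulation.

    ``sim`` is the output of
    :func:`ppdwear.synthetic_data.simulate_window_cohort`; every person is
    summarized over the common window through the standard daily-wear
    derivation, and demographics are attached for modelling.
    """
    daily = derive_daily_wear(sim["steps_hourly"])
    if not sim["sleep_daily"].empty:
        daily = attach_sleep(daily, sim["sleep_daily"])
    start, end = sim["window"]
    rows = []
    for r in sim["persons"].itertuples(index=False):
        pa = PeriodAssignment(r.person_id, period, start, end)
        s = summarize_period(r.person_id, pa, daily, start)
        rows.append(
            {
                "person_id": r.person_id,
                "period": period.value,
                "pct_worn": s.pct_worn,
                "pct_sleep_worn": s.pct_sleep_worn,
                "max_consecutive_worn": s.max_consecutive_worn,
                "mean_hours_on_worn_days": s.mean_hours_on_worn_days,
                "empty": s.empty,
                "cohort": r.cohort,
                "age": r.age,
                "race": r.race,
            }
        )
    return pd.DataFrame(rows)


def daily_hours_frame(sim: dict) -> pd.DataFrame:
    """Worn-day hours with demographics, for the hours-per-day mixed model."""
    daily = derive_daily_wear(sim["steps_hourly"])
    return daily.loc[daily["worn"]].merge(
        sim["persons"], on="person_id", how="inner"
    )


def run_pipeline(
    input_dir: str | Path,
    out_dir: str | Path,
    config: AnalysisConfig | None = None,
) -> dict:
    """Run the full analysis and write all artifacts. Returns the report."""
    config = config or AnalysisConfig()
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    inputs = load_inputs(input_dir)
    phenotypes = phenotype_cohort(inputs, config)
    daily = compute_daily(inputs, config)
    summaries, kept = compute_summaries(inputs, phenotypes, daily)
    if not kept:
        raise StatsError("no eligible persons remain after filtering")
    persons_df = _person_frame(kept, phenotypes)
    daily_periods = _daily_with_period(daily, kept, phenotypes)
    comparisons = compute_comparisons(
        summaries, persons_df, daily_periods, config,
        include_sleep=inputs.sleep_daily is not None,
    )
    correlations = compute_correlations(summaries, persons_df)
    report = build_report(
        persons_df, summaries, config.suppression_threshold
    )
    report["sleep_metrics_available"] = inputs.sleep_daily is not None

    summaries.to_csv(out / "summaries.csv", index=False)
    comparisons.to_csv(out / "comparison.csv", index=False)
    correlations.to_csv(out / "correlations.csv", index=False)
    (out / "report.json").write_text(json.dumps(report, indent=2, sort_keys=True))
    logger.info("wrote artifacts to %s", out)
    return report
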