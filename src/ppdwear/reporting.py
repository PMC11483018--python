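"""Descriptive cohort report: women, person-days, age, race/ethnicity.

Counts are broken down by cohort and by cohort x period; percentages are
printed to one decimal. Race/ethnicity cells below the suppression
threshold (default 20, mirroring research-program dissemination policy
for re-identification risk) are masked.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .phenotyping import Cohort, Period

__all__ = ["percentage", "build_report"]

EVERYONE = "Everyone"
SUPPRESSED = "suppressed"


def percentage(count: float, total: float, decimals: int = 1) -> float:
    """Printed-precision percentage: 100 * count / total, rounded."""
    if total == 0:
        return 0.0
    return round(100.0 * count / total, decimals)


def _age_stats(ages: pd.Series) -> dict:
    if ages.empty:
        return {"median": None, "iqr": None}
    q1, med, q3 = (
        float(v) for v in np.percentile(ages.astype(float), [25, 50, 75])
    )  # linear interpolation (type-7)
    return {"median": round(med, 1), "iqr": [round(q1, 1), round(q3, 1)]}


def build_report(
    persons: pd.DataFrame,
    summaries: pd.DataFrame,
    suppression_threshold: int = 20,
) -> dict:
    """Assemble the descriptive cohort report.

    ``persons`` needs columns person_id, cohort, age, race; ``summaries``
    is the person x period table (``n_days_with_data`` supplies the
    person-day counts). Deterministic: the same inputs always produce an
    identical report.
    """
    persons = persons.copy()
    persons["cohort"] = persons["cohort"].astype(str)
    merged = summaries.merge(
        persons[["person_id", "cohort"]], on="person_id", how="inner"
    )
    total_women = len(persons)
    total_days = int(merged["n_days_with_data"].sum())

    cohort_block = {}
    for label, sub_p, sub_s in (
        (EVERYONE, persons, merged),
        (Cohort.PPD.value, persons[persons["cohort"] == Cohort.PPD.value],
         merged[merged["cohort"] == Cohort.PPD.value]),
        (Cohort.NON_PPD.value,
         persons[persons["cohort"] == Cohort.NON_PPD.value],
         merged[merged["cohort"] == Cohort.NON_PPD.value]),
    ):
        n_days = int(sub_s["n_days_with_data"].sum())
        cohort_block[label] = {
            "n_women": len(sub_p),
            "pct_women": percentage(len(sub_p), total_women),
            "n_days": n_days,
            "pct_days": percentage(n_days, total_days),
        }

    period_block: dict[str, dict[str, dict]] = {}
    for label in (EVERYONE, Cohort.PPD.value, Cohort.NON_PPD.value):
        sub = merged if label == EVERYONE else merged[merged["cohort"] == label]
        denom = int(sub["n_days_with_data"].sum())
        period_block[label] = {}
        for period in Period:
            days = int(
                sub.loc[sub["period"] == period.value, "n_days_with_data"].sum()
            )
            period_block[label][period.value] = {
                "n_days": days,
                "pct_days": percentage(days, denom),
            }

    age_block = {
        EVERYONE: _age_stats(persons["age"]),
        Cohort.PPD.value: _age_stats(
            persons.loc[persons["cohort"] == Cohort.PPD.value, "age"]
        ),
        Cohort.NON_PPD.value: _age_stats(
            persons.loc[persons["cohort"] == Cohort.NON_PPD.value, "age"]
        ),
    }

    race_block: dict[str, dict[str, dict]] = {}
    for label in (EVERYONE, Cohort.PPD.value, Cohort.NON_PPD.value):
        sub = persons if label == EVERYONE else persons[persons["cohort"] == label]
        race_block[label] = {}
        for level, count in sorted(sub["race"].value_counts().items()):
            if count < suppression_threshold:
                race_block[label][level] = {"n": SUPPRESSED, "pct": SUPPRESSED}
            else:
                race_block[label][level] = {
                    "n": int(count),
                    "pct": percentage(count, len(sub)),
                }

    return {
        "cohorts": cohort_block,
        "period_days": period_block,
        "age": age_block,
        "race_ethnicity": race_block,
        "suppression_threshold": suppression_threshold,
    }
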