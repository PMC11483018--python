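"""Analysis configuration: window lengths, wear thresholds, reporting options.

All windows are whole calendar days and all intervals are closed
([start, end] inclusive). Two years / 24 months are fixed at 730 days so
period lengths do not depend on leap years.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from pathlib import Path

import yaml


class ConfigurationError(ValueError):
    """Raised when a configuration value is outside its legal range."""


@dataclass(frozen=True)
class AnalysisConfig:
    """Tunable parameters of the phenotyping and wear-time analysis.

    Parameters
    ----------
    ppd_window_months
        How long after delivery a qualifying depression event still counts
        as postpartum depression (24 months == 730 days).
    ppd_equivalent_offset_days
        Index-date offset for the non-PPD pseudo window: the median
        delivery-to-diagnosis delay of the PPD cohort (58 days).
    ppd_pre_days, ppd_post_days
        Extent of the PPD window around the index date. For the PPD cohort
        the window is [index - ppd_pre_days, index + ppd_post_days]; for the
        non-PPD cohort the 14 days before the index are dropped entirely
        because those women never experienced depression onset, so the
        window is [index, index + ppd_post_days].
    prepregnancy_lookback_days
        Pre-pregnancy period starts this many days before the index date.
    wear_hour_min_steps
        A clock hour counts as a wear hour when it has at least this many
        recorded steps.
    worn_day_min_hours
        A day counts as worn when it has at least this many wear hours.
    suppression_threshold
        Descriptive-report cells with fewer persons than this are masked.
    emm_weights
        Reference-grid weighting over non-focus factors when computing
        adjusted means: "equal" (each level weighted equally) or
        "proportional" (observed level frequencies).
    """

    ppd_window_months: int = 24
    ppd_equivalent_offset_days: int = 58
    ppd_pre_days: int = 14
    ppd_post_days: int = 30
    prepregnancy_lookback_days: int = 730
    wear_hour_min_steps: int = 1
    worn_day_min_hours: int = 1
    suppression_threshold: int = 20
    emm_weights: str = "equal"

    def __post_init__(self) -> None:
        if self.ppd_equivalent_offset_days < 0:
            raise ConfigurationError(
                "ppd_equivalent_offset_days must be non-negative, got "
                f"{self.ppd_equivalent_offset_days}"
            )
        for name in ("ppd_window_months", "ppd_pre_days", "ppd_post_days",
                     "prepregnancy_lookback_days", "wear_hour_min_steps",
                     "worn_day_min_hours"):
            if getattr(self, name) < 0:
                raise ConfigurationError(f"{name} must be non-negative")
        if self.emm_weights not in ("equal", "proportional"):
            raise ConfigurationError(
                f"emm_weights must be 'equal' or 'proportional', got "
                f"{self.emm_weights!r}"
            )

    @property
    def ppd_window_days(self) -> int:
        """Postpartum qualification window in days (24 months -> 730)."""
        return round(self.ppd_window_months * 730 / 24)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "AnalysisConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ConfigurationError(
                f"unknown config keys: {sorted(unknown)}; known: {sorted(known)}"
            )
        return cls(**raw)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(
            yaml.safe_dump(dataclasses.asdict(self), sort_keys=False)
        )
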