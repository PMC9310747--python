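"""Channel registry and analysis configuration.

The four monitored channels — heart rate (HR), respiratory rate (RR),
peripheral oxygen saturation (SPO2) and systolic blood pressure (SBP) —
are fixed configuration, as are their physiologic plausibility ranges.
Values outside a channel's range are treated as sensor artefact on ingest.

:class:`AnalysisConfig` collects every tunable boundary of the analysis
(day/night clock boundaries, the 5-min episode merge gap, the 60-min
last-observation-carried-forward cap, the 4 %/s SpO2 artefact slope limit,
the ECG quality-correlation threshold, the blood-pressure measurement
schedule and the 96-h monitoring cap) so that no stage hard-codes them.
"""

from __future__ import annotations

import datetime
from typing import Literal

import yaml
from pydantic import BaseModel, Field, model_validator

ChannelName = Literal["HR", "RR", "SPO2", "SBP"]

#: Channels that produce a value every monitored minute (episode detection
#: runs on their minute grid).  SBP is intermittent and handled separately.
CONTINUOUS_CHANNELS: tuple[ChannelName, ...] = ("HR", "RR", "SPO2")
ALL_CHANNELS: tuple[ChannelName, ...] = ("HR", "RR", "SPO2", "SBP")


class VitalChannel(BaseModel):
    """One monitored vital sign and its fixed plausibility range."""

    name: ChannelName
    units: str
    plausibility_range: tuple[float, float]

    model_config = {"frozen": True}

    def is_plausible(self, value: float) -> bool:
        lo, hi = self.plausibility_range
        return lo <= value <= hi


CHANNELS: dict[str, VitalChannel] = {
    "HR": VitalChannel(name="HR", units="beats/min", plausibility_range=(10.0, 300.0)),
    "RR": VitalChannel(name="RR", units="breaths/min", plausibility_range=(0.0, 80.0)),
    "SPO2": VitalChannel(name="SPO2", units="%", plausibility_range=(40.0, 100.0)),
    "SBP": VitalChannel(name="SBP", units="mmHg", plausibility_range=(30.0, 300.0)),
}


class AnalysisConfig(BaseModel):
    """All tunable boundaries of the monitoring analysis.

    Defaults mirror the study design: day runs 07:00–21:59 and night
    22:00–06:59; abnormality stretches less than 5 min apart merge into one
    episode; gaps are filled by carrying the last observation forward for at
    most 60 min; an SpO2 change steeper than 4 %/s is artefact; blood
    pressure is scheduled every 30 min by day and 60 min by night; and
    monitoring is capped at 96 h.
    """

    day_start: datetime.time = datetime.time(7, 0)
    night_start: datetime.time = datetime.time(22, 0)
    merge_gap_minutes: int = 5
    locf_max_minutes: int = 60
    #: channels to which LOCF gap filling applies
    locf_channels: tuple[ChannelName, ...] = ("HR", "RR", "SPO2", "SBP")
    spo2_slope_limit: float = 4.0  # % per second
    qrs_correlation_threshold: float = Field(0.8, gt=0.0, lt=1.0)
    bp_day_interval: int = 30  # minutes
    bp_night_interval: int = 60  # minutes
    bp_min_consecutive: int = 2
    max_monitoring_hours: int = 96
    #: whether episode persistence is tested on merged condition-true time
    #: ("merged"), on the merged span including gaps ("span"), or before
    #: merging ("premerge")
    persistence_mode: Literal["merged", "span", "premerge"] = "merged"
    #: gate values outside the channel plausibility range on ingest
    plausibility_gate: bool = True
    #: 24-h normalization uses elapsed window length; set True to divide by
    #: minutes actually covered by data instead
    coverage_based_normalization: bool = False
    #: optional floor on monitoring duration (minutes); 0 disables
    min_monitoring_minutes: int = 0
    #: day/night tables renormalize to the stratum length (per-15 h day,
    #: per-9 h night); set "per24h" to scale both strata to 24 h instead
    daynight_normalization: Literal["stratum", "per24h"] = "stratum"

    @model_validator(mode="after")
    def _check(self) -> "AnalysisConfig":
        if not self.day_start < self.night_start:
            raise ValueError("day_start must precede night_start within a calendar day")
        for attr in ("merge_gap_minutes", "locf_max_minutes", "bp_day_interval",
                     "bp_night_interval", "bp_min_consecutive", "max_monitoring_hours"):
            if getattr(self, attr) <= 0:
                raise ValueError(f"{attr} must be strictly positive")
        if self.spo2_slope_limit <= 0:
            raise ValueError("spo2_slope_limit must be strictly positive")
        return self

    # -- serialization ----------------------------------------------------
    @classmethod
    def from_file(cls, path) -> "AnalysisConfig":
        """Load a config from a YAML (or JSON, a YAML subset) file."""
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls.model_validate(data)

    def to_yaml(self) -> str:
        data = self.model_dump(mode="json")
        return yaml.safe_dump(data, sort_keys=True)


#: number of minutes in the day stratum (07:00–21:59) and night stratum
DAY_STRATUM_MINUTES = 15 * 60
NIGHT_STRATUM_MINUTES = 9 * 60
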