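"""Patient grouping, exposure windows, 24-h normalization and day/night
stratification.

Patients fall into three groups by the timing of their first serious
adverse event (SAE): ``SAE_DURING`` (first SAE inside the monitoring
period), ``SAE_AFTER`` (first SAE after monitoring but within 30
postoperative days) and ``NO_SAE``.  Only vital signs preceding the first
SAE are analysed, so the exposure window of a SAE-during patient is the up
to 24 h immediately before the SAE, while the other groups contribute
their whole monitoring period.  Because windows differ in length, episode
counts and durations are normalized to a 24-h period: a patient whose
normalized episode count is below one is not counted as having that
abnormality.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Dict, Optional

import numpy as np

from .config import AnalysisConfig, DAY_STRATUM_MINUTES, NIGHT_STRATUM_MINUTES
from .series import MinuteGrid, SampleSeries

MINUTE = np.timedelta64(60, "s")
DAY_24H = np.timedelta64(24 * 3600, "s")


class GroupLabel(str, enum.Enum):
    SAE_DURING = "SAE_DURING"
    SAE_AFTER = "SAE_AFTER"
    NO_SAE = "NO_SAE"


GROUP_ORDER = (GroupLabel.SAE_DURING, GroupLabel.SAE_AFTER, GroupLabel.NO_SAE)


@dataclass
class PatientRecord:
    """One patient's streams, monitoring window and first-SAE time."""

    patient_id: str
    monitoring_start: np.datetime64
    monitoring_end: np.datetime64
    series: Dict[str, SampleSeries] = field(default_factory=dict)
    first_sae_time: Optional[np.datetime64] = None

    def __post_init__(self):
        self.monitoring_start = np.datetime64(self.monitoring_start, "s")
        self.monitoring_end = np.datetime64(self.monitoring_end, "s")
        if self.first_sae_time is not None:
            self.first_sae_time = np.datetime64(self.first_sae_time, "s")
        if self.monitoring_end <= self.monitoring_start:
            raise ValueError(f"{self.patient_id}: monitoring window is empty")

    @property
    def monitoring_minutes(self) -> float:
        return float((self.monitoring_end - self.monitoring_start)
                     / np.timedelta64(1, "s")) / 60.0


@dataclass(frozen=True)
class ExposureWindow:
    """The analysed time interval and its 24-h normalization factor."""

    start: np.datetime64
    end: np.datetime64
    normalization_factor: float
    monitored_minutes: Optional[float] = None

    @property
    def length_minutes(self) -> float:
        return float((self.end - self.start) / np.timedelta64(1, "s")) / 60.0


def assign_group(patient: PatientRecord, followup_days: int = 30) -> GroupLabel:
    """Label a patient by the timing of the first SAE.

    The 30-day follow-up clock starts at monitoring start (arrival on the
    ward); a first SAE after the follow-up horizon counts as no SAE.
    """
    sae = patient.first_sae_time
    if sae is None:
        return GroupLabel.NO_SAE
    if sae < patient.monitoring_start:
        raise ValueError(f"{patient.patient_id}: SAE precedes monitoring")
    if sae <= patient.monitoring_end:
        return GroupLabel.SAE_DURING
    horizon = patient.monitoring_start + np.timedelta64(followup_days * 86400, "s")
    if sae <= horizon:
        return GroupLabel.SAE_AFTER
    return GroupLabel.NO_SAE


def exposure_window(
    patient: PatientRecord,
    label: GroupLabel,
    monitored_minutes: Optional[float] = None,
    coverage_based: bool = False,
) -> ExposureWindow:
    """Build the analysed window and its normalization factor.

    SAE-during patients contribute the up-to-24-h interval ending at the
    first SAE (factor 24 h / window length when shorter than 24 h); the
    other groups contribute the full monitoring period scaled by
    24 h / monitoring time.  With ``coverage_based`` the factor divides by
    minutes actually covered by data instead of elapsed window length.
    """
    if label is GroupLabel.SAE_DURING:
        end = patient.first_sae_time
        start = max(patient.monitoring_start, end - DAY_24H)
    else:
        start, end = patient.monitoring_start, patient.monitoring_end
    length_min = float((end - start) / np.timedelta64(1, "s")) / 60.0
    if length_min <= 0:
        raise ValueError(f"{patient.patient_id}: zero-length exposure window")
    denom = length_min
    if coverage_based:
        if monitored_minutes is None:
            raise ValueError("coverage-based normalization needs monitored_minutes")
        if monitored_minutes <= 0:
            raise ValueError(f"{patient.patient_id}: no monitored minutes in window")
        denom = monitored_minutes
    return ExposureWindow(
        start=start,
        end=end,
        normalization_factor=1440.0 / denom,
        monitored_minutes=monitored_minutes,
    )


def normalized_counts(
    n_episodes: float, condition_minutes: float, window: ExposureWindow
) -> tuple[float, float]:
    """Scale raw episode count and abnormal minutes to a 24-h period."""
    f = window.normalization_factor
    return n_episodes * f, condition_minutes * f


def has_abnormality(normalized_count: float) -> bool:
    """A patient counts as having the abnormality at >= 1 episode per 24 h."""
    return normalized_count >= 1.0


# ---------------------------------------------------------------------------
# day / night stratification
# ---------------------------------------------------------------------------

def _minutes_of_day(start: np.datetime64, n_minutes: int) -> np.ndarray:
    start = np.datetime64(start, "s")
    start_mod = int((start - start.astype("datetime64[D]"))
                    / np.timedelta64(1, "s")) // 60
    return (start_mod + np.arange(n_minutes)) % 1440


def day_mask(start: np.datetime64, n_minutes: int, config: AnalysisConfig) -> np.ndarray:
    """True for minutes whose clock time lies in the day stratum."""
    mod = _minutes_of_day(start, n_minutes)
    d0 = config.day_start.hour * 60 + config.day_start.minute
    n0 = config.night_start.hour * 60 + config.night_start.minute
    return (mod >= d0) & (mod < n0)


def day_night_partition(
    window: ExposureWindow, config: AnalysisConfig
) -> tuple[int, int]:
    """Minutes of the window falling in the day vs night stratum.

    Every minute lands in exactly one stratum (day 07:00-21:59, night
    22:00-06:59 by default), so the two counts always sum to the window
    length.
    """
    n = int(round(window.length_minutes))
    mask = day_mask(window.start, n, config)
    day = int(mask.sum())
    return day, n - day


def stratum_normalization_factor(
    stratum_minutes_in_window: float, stratum: str, config: AnalysisConfig
) -> float:
    """Normalization for a day/night stratum.

    Default scales to one full stratum (900 day minutes / 540 night
    minutes); the ``per24h`` mode scales to 24 h instead.
    """
    if stratum_minutes_in_window <= 0:
        raise ValueError("empty stratum")
    if config.daynight_normalization == "per24h":
        return 1440.0 / stratum_minutes_in_window
    target = DAY_STRATUM_MINUTES if stratum == "day" else NIGHT_STRATUM_MINUTES
    return target / stratum_minutes_in_window


# ---------------------------------------------------------------------------
# contingency tables and duration summaries
# ---------------------------------------------------------------------------

@dataclass
class ContingencyTable:
    """Patients with/without >= 1 normalized abnormality, per group."""

    groups: tuple
    with_abnormality: np.ndarray
    without_abnormality: np.ndarray

    def __post_init__(self):
        self.with_abnormality = np.asarray(self.with_abnormality, dtype=int)
        self.without_abnormality = np.asarray(self.without_abnormality, dtype=int)

    @property
    def group_sizes(self) -> np.ndarray:
        return self.with_abnormality + self.without_abnormality

    def to_array(self) -> np.ndarray:
        return np.vstack([self.with_abnormality, self.without_abnormality])


def build_contingency(flags_by_group: Dict[GroupLabel, list]) -> ContingencyTable:
    """Tally has-abnormality flags into a 2 x k table (groups as columns)."""
    groups = tuple(g for g in GROUP_ORDER if g in flags_by_group)
    if len(groups) < 2:
        raise ValueError("degenerate table: need at least two groups")
    withs, withouts = [], []
    for g in groups:
        flags = list(flags_by_group[g])
        if len(flags) == 0:
            raise ValueError(f"degenerate table: empty group {g.value}")
        w = sum(bool(f) for f in flags)
        withs.append(w)
        withouts.append(len(flags) - w)
    return ContingencyTable(groups=groups,
                            with_abnormality=np.array(withs),
                            without_abnormality=np.array(withouts))
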