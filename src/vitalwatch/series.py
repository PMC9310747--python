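"""In-memory containers for vital-sign measurements.

A :class:`SampleSeries` holds one channel's raw timestamped samples with a
per-sample quality flag; a :class:`MinuteGrid` holds one channel's
per-minute averages on a grid anchored at the monitoring start.  Both are
thin dataclasses over numpy arrays so that per-cohort simulation and
detection stay cheap.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .config import CHANNELS

# per-sample / per-minute quality codes
OBSERVED = 0
LOCF_FILLED = 1
ARTIFACT_REJECTED = 2
MISSING = 3

QUALITY_NAMES = {
    OBSERVED: "observed",
    LOCF_FILLED: "locf_filled",
    ARTIFACT_REJECTED: "artifact_rejected",
    MISSING: "missing",
}


@dataclass
class SampleSeries:
    """One channel's timestamped measurements with quality flags.

    Parameters
    ----------
    channel
        Channel name (``HR``/``RR``/``SPO2``/``SBP``).
    times
        ``datetime64[s]`` array, strictly increasing.
    values
        Measurement values in channel units.
    quality
        Per-sample code (:data:`OBSERVED` / :data:`ARTIFACT_REJECTED` ...).
        Defaults to all-observed.
    """

    channel: str
    times: np.ndarray
    values: np.ndarray
    quality: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype="datetime64[s]")
        self.values = np.asarray(self.values, dtype=float)
        if self.quality is None:
            self.quality = np.zeros(len(self.values), dtype=np.int8)
        else:
            self.quality = np.asarray(self.quality, dtype=np.int8)
        if not (len(self.times) == len(self.values) == len(self.quality)):
            raise ValueError("times, values and quality must have equal length")
        if len(self.times) > 1 and not (np.diff(self.times.astype("int64")) > 0).all():
            raise ValueError("timestamps must be strictly increasing")

    def __len__(self) -> int:
        return len(self.values)

    @property
    def retained(self) -> np.ndarray:
        """Boolean mask of samples not rejected as artefact."""
        return self.quality != ARTIFACT_REJECTED

    def retained_only(self) -> "SampleSeries":
        m = self.retained
        return SampleSeries(self.channel, self.times[m], self.values[m], self.quality[m])


@dataclass
class MinuteGrid:
    """One channel's per-minute values on a grid anchored at monitoring start.

    ``values`` is NaN where a minute has no data; ``quality`` distinguishes
    observed minutes from LOCF-filled and missing ones; ``source_minute``
    records, for a filled minute, the index of the observed minute its value
    was carried from (-1 otherwise).
    """

    channel: str
    start: np.datetime64  # minute-aligned grid origin
    values: np.ndarray
    quality: np.ndarray = field(default=None)  # type: ignore[assignment]
    source_minute: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self):
        self.start = np.datetime64(self.start, "s")
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.values)
        if self.quality is None:
            q = np.where(np.isnan(self.values), MISSING, OBSERVED)
            self.quality = q.astype(np.int8)
        else:
            self.quality = np.asarray(self.quality, dtype=np.int8)
        if self.source_minute is None:
            self.source_minute = np.full(n, -1, dtype=np.int64)
        else:
            self.source_minute = np.asarray(self.source_minute, dtype=np.int64)

    def __len__(self) -> int:
        return len(self.values)

    @property
    def missing(self) -> np.ndarray:
        return np.isnan(self.values)

    def minute_of_day(self) -> np.ndarray:
        """Clock minute-of-day (0..1439) for each grid minute."""
        start_mod = int(
            (self.start - self.start.astype("datetime64[D]")).astype("timedelta64[s]").astype(int)
            // 60
        )
        return (start_mod + np.arange(len(self.values))) % 1440

    def slice(self, start_minute: int, end_minute: int) -> "MinuteGrid":
        """Sub-grid for minutes [start_minute, end_minute)."""
        s, e = int(start_minute), int(end_minute)
        return MinuteGrid(
            self.channel,
            self.start + np.timedelta64(60 * s, "s"),
            self.values[s:e],
            self.quality[s:e],
            self.source_minute[s:e] - s,
        )


def validate_channel(name: str) -> str:
    if name not in CHANNELS:
        raise ValueError(f"unknown channel {name!r}; expected one of {sorted(CHANNELS)}")
    return name
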