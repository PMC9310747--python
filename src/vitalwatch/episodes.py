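"""Threshold-episode detection with duration x severity tiers.

A *run* is a maximal stretch of consecutive minutes on which the tier's
condition holds (missing minutes terminate a run; all inequalities are
strict).  Runs closer than the merge gap — by default, less than 5 min
apart — coalesce into one, with the gap minutes not counted as abnormal
time.  A merged run whose condition-true time reaches the tier's minimum
persistence becomes an *episode*.

Systolic blood pressure is measured intermittently, so its tiers count
consecutive abnormal measurements ("two in a row") rather than minutes and
bypass the minute-grid machinery entirely.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from .series import MinuteGrid, SampleSeries
from .tiers import ThresholdTier


@dataclass(frozen=True)
class Run:
    """A maximal condition-true stretch of grid minutes (inclusive ends)."""

    channel: str
    start: int
    end: int
    true_minutes: int

    @property
    def span(self) -> int:
        return self.end - self.start + 1


@dataclass(frozen=True)
class Episode:
    """A detected abnormality interval qualifying under its tier."""

    tier: ThresholdTier
    start: int  # minute index (continuous) / measurement index (SBP)
    end: int
    duration: float  # condition-true minutes (SBP: span between measurements)
    n_merged: int = 1


def _condition_mask(grid: MinuteGrid, direction: str, threshold: float) -> np.ndarray:
    # NaN minutes compare False under both directions, which is exactly the
    # "missing minutes never satisfy the condition" rule
    with np.errstate(invalid="ignore"):
        if direction == "below":
            return grid.values < threshold
        if direction == "above":
            return grid.values > threshold
    raise ValueError(f"unknown direction {direction!r}")


def detect_runs(
    grid: MinuteGrid, channel: str, direction: str, threshold: float
) -> list[Run]:
    """Maximal runs of minutes strictly beyond ``threshold``.

    NaN (missing) minutes never satisfy the condition and therefore break
    runs; LOCF-filled minutes count like observed ones.
    """
    if grid.channel != channel:
        raise ValueError(f"grid holds {grid.channel}, not {channel}")
    cond = _condition_mask(grid, direction, threshold)
    if not cond.any():
        return []
    padded = np.diff(np.concatenate(([0], cond.view(np.int8), [0])))
    starts = np.flatnonzero(padded == 1)
    ends = np.flatnonzero(padded == -1) - 1
    return [
        Run(channel=channel, start=int(s), end=int(e), true_minutes=int(e - s + 1))
        for s, e in zip(starts, ends)
    ]


def merge_runs(runs: Sequence[Run], gap: int = 5) -> list[Run]:
    """Coalesce runs separated by strictly less than ``gap`` minutes.

    Two runs separated by exactly ``gap`` minutes stay distinct.  Merged
    ``true_minutes`` is the sum of the members' condition-true minutes; the
    separating minutes do not count as abnormal time.
    """
    if not runs:
        return []
    out = [runs[0]]
    for run in runs[1:]:
        prev = out[-1]
        if run.start <= prev.end:
            raise ValueError("runs must be sorted and non-overlapping")
        separation = run.start - prev.end - 1
        if separation < gap:
            out[-1] = Run(
                channel=prev.channel,
                start=prev.start,
                end=run.end,
                true_minutes=prev.true_minutes + run.true_minutes,
            )
        else:
            out.append(run)
    return out


def classify_episodes(
    merged_runs: Iterable[Run], tier: ThresholdTier, mode: str = "merged"
) -> list[Episode]:
    """Emit an episode for each merged run meeting the tier's persistence.

    ``mode`` selects what the persistence requirement is tested against:
    ``"merged"`` (default) uses condition-true minutes after merging,
    ``"span"`` the merged run's full span including gap minutes.
    """
    if tier.is_bp:
        raise ValueError("SBP tiers count consecutive measurements; use detect_bp_episodes")
    episodes = []
    for run in merged_runs:
        qualifying = run.true_minutes if mode == "merged" else run.span
        if qualifying >= tier.min_persistence:
            episodes.append(
                Episode(
                    tier=tier,
                    start=run.start,
                    end=run.end,
                    duration=float(run.true_minutes),
                    n_merged=1,
                )
            )
    return episodes


def detect_channel_episodes(
    grid: MinuteGrid,
    tier: ThresholdTier,
    merge_gap: int = 5,
    persistence_mode: str = "merged",
) -> list[Episode]:
    """Full continuous-channel detection: runs -> merge -> qualify.

    With ``persistence_mode="premerge"`` runs must individually meet the
    persistence requirement before merging; otherwise merging happens first
    (see :func:`classify_episodes` for "merged" vs "span").
    """
    raw = detect_runs(grid, tier.channel, tier.direction, tier.threshold)
    runs = raw
    if persistence_mode == "premerge":
        runs = [r for r in runs if r.true_minutes >= tier.min_persistence]
        merged = merge_runs(runs, merge_gap)
        return classify_episodes(merged, tier, mode="merged")
    merged = merge_runs(runs, merge_gap)
    episodes = classify_episodes(merged, tier, mode=persistence_mode)
    # annotate how many pre-merge runs each episode absorbed
    out = []
    for ep in episodes:
        n_members = sum(1 for r in raw if ep.start <= r.start and r.end <= ep.end)
        out.append(
            Episode(
                tier=ep.tier,
                start=ep.start,
                end=ep.end,
                duration=ep.duration,
                n_merged=max(n_members, 1),
            )
        )
    return out


def detect_bp_episodes(sbp: SampleSeries, tier: ThresholdTier) -> list[Episode]:
    """Episodes of consecutive abnormal blood-pressure measurements.

    Each maximal stretch of at least ``tier.min_consecutive`` successive
    measurements strictly beyond the threshold is one episode ("two in a
    row"), so three abnormal measurements in a row are a single episode.
    Consecutiveness is defined on successive retained measurements, not on
    minutes: the intermittent schedule means gaps in time are expected.
    Episode duration is the span in minutes between the first and last
    qualifying measurement.
    """
    if not tier.is_bp:
        raise ValueError("tier is not an SBP tier")
    kept = sbp.retained_only()
    if len(kept) == 0:
        return []
    cond = tier.condition(kept.values)
    padded = np.diff(np.concatenate(([0], cond.view(np.int8), [0])))
    starts = np.flatnonzero(padded == 1)
    ends = np.flatnonzero(padded == -1) - 1
    episodes = []
    t = kept.times.astype("int64")
    for s, e in zip(starts, ends):
        count = e - s + 1
        if count >= tier.min_consecutive:
            duration_min = (t[e] - t[s]) / 60.0
            episodes.append(
                Episode(tier=tier, start=int(s), end=int(e), duration=float(duration_min),
                        n_merged=int(count))
            )
    return episodes


def cumulative_duration(
    grid: MinuteGrid,
    channel: str,
    direction: str,
    threshold: float,
    window: tuple[int, int] | None = None,
    minute_mask: np.ndarray | None = None,
) -> int:
    """Count condition-true minutes, with no persistence or merge rule.

    ``window`` restricts to grid minutes [start, end); ``minute_mask``
    additionally restricts to a boolean subset (used for day/night strata).
    """
    cond = _condition_mask(grid, direction, threshold)
    if grid.channel != channel:
        raise ValueError(f"grid holds {grid.channel}, not {channel}")
    if window is not None:
        sel = np.zeros(len(cond), dtype=bool)
        sel[window[0] : window[1]] = True
        cond = cond & sel
    if minute_mask is not None:
        cond = cond & minute_mask
    return int(cond.sum())
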