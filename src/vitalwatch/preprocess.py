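"""Signal cleaning: plausibility gating, SpO2 artefact rejection,
per-minute averaging and capped last-observation-carried-forward filling.

The cleaning order used by the pipeline is: (1) gate physiologically
implausible values on ingest, (2) reject SpO2 samples whose rate of change
exceeds 4 %/s, (3) average retained samples onto the minute grid anchored
at monitoring start, (4) fill gaps by carrying the last observed minute
forward for at most 60 min.  Rejected samples never enter any downstream
computation; filled minutes keep a pointer to the minute they were copied
from.
"""

from __future__ import annotations

import numpy as np

from .config import CHANNELS
from .series import (
    ARTIFACT_REJECTED,
    LOCF_FILLED,
    MISSING,
    OBSERVED,
    MinuteGrid,
    SampleSeries,
)


def apply_plausibility_gate(series: SampleSeries) -> SampleSeries:
    """Flag samples outside the channel's plausibility range as artefact.

    The range gate is a fixed per-channel configuration (HR 10–300 beats/min,
    RR 0–80 breaths/min, SpO2 40–100 %, SBP 30–300 mmHg), not inferred from
    the data.
    """
    lo, hi = CHANNELS[series.channel].plausibility_range
    quality = series.quality.copy()
    bad = (series.values < lo) | (series.values > hi) | np.isnan(series.values)
    quality[bad & (quality == OBSERVED)] = ARTIFACT_REJECTED
    return SampleSeries(series.channel, series.times, series.values, quality)


def filter_spo2_artifacts(
    series: SampleSeries, slope_limit: float = 4.0, reset_after: int = 3
) -> SampleSeries:
    """Reject SpO2 samples that change faster than ``slope_limit`` %/s.

    The comparison baseline for each sample is the previous *retained*
    sample, so a single spike is rejected once rather than cascading into
    rejections of the normal samples that follow it.  Already-rejected
    samples (e.g. by the plausibility gate) are skipped entirely.  After
    ``reset_after`` consecutive rejections the next sample is accepted
    unconditionally: a level sustained that long is a real change of state,
    not a transient, and an unbounded baseline would otherwise discard the
    remainder of the stream.  The operation is idempotent.
    """
    if series.channel != "SPO2":
        raise ValueError("slope filter applies to the SPO2 channel")
    n = len(series)
    quality = series.quality.copy()
    if n < 2:
        return SampleSeries(series.channel, series.times, series.values, quality)

    t = series.times.astype("int64")  # seconds
    v = series.values
    # fast path: nothing rejected yet and no successive-sample violation
    if (quality != ARTIFACT_REJECTED).all():
        dt = np.diff(t).astype(float)
        with np.errstate(invalid="ignore"):
            if not (np.abs(np.diff(v)) / dt > slope_limit).any():
                return SampleSeries(series.channel, series.times, series.values, quality)
    last = -1  # index of previous retained sample
    consec_bad = 0
    for i in range(n):
        if quality[i] == ARTIFACT_REJECTED:
            consec_bad += 1
            continue
        if last >= 0 and consec_bad < reset_after:
            dt = t[i] - t[last]
            if dt > 0 and abs(v[i] - v[last]) / dt > slope_limit:
                quality[i] = ARTIFACT_REJECTED
                consec_bad += 1
                continue
        last = i
        consec_bad = 0
    return SampleSeries(series.channel, series.times, series.values, quality)


def to_minute_grid(series: SampleSeries, window: tuple) -> MinuteGrid:
    """Average retained samples onto a per-minute grid over ``window``.

    Bins are left-closed right-open minutes anchored at the window start;
    a minute's value is the arithmetic mean of the non-rejected samples
    falling in it, or NaN if there are none.
    """
    start = np.datetime64(window[0], "s")
    end = np.datetime64(window[1], "s")
    span_s = (end - start).astype("timedelta64[s]").astype(int)
    if span_s <= 0:
        return MinuteGrid(series.channel, start, np.empty(0))
    n_minutes = -(-span_s // 60)  # ceil: a partial trailing minute is a bin

    m = series.retained
    offs = (series.times[m] - start).astype("timedelta64[s]").astype(int)
    vals = series.values[m]
    inside = (offs >= 0) & (offs < span_s)
    bins = offs[inside] // 60
    sums = np.bincount(bins, weights=vals[inside], minlength=n_minutes)
    counts = np.bincount(bins, minlength=n_minutes)
    with np.errstate(invalid="ignore"):
        values = np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)
    return MinuteGrid(series.channel, start, values)


def locf_fill(grid: MinuteGrid, max_gap: int = 60) -> MinuteGrid:
    """Carry the last observed minute forward across gaps of at most ``max_gap``.

    A missing minute ``m`` takes the value of the most recent observed
    minute ``m0`` iff ``m - m0 <= max_gap``.  Leading missing minutes are
    never filled, observed minutes are never changed, and filled minutes
    are flagged with the index of their source minute.
    """
    if max_gap <= 0:
        raise ValueError("max_gap must be strictly positive")
    n = len(grid)
    values = grid.values.copy()
    quality = grid.quality.copy()
    source = grid.source_minute.copy()
    if n == 0:
        return MinuteGrid(grid.channel, grid.start, values, quality, source)

    observed = quality == OBSERVED
    idx = np.arange(n)
    last_obs = np.where(observed, idx, -1)
    last_obs = np.maximum.accumulate(last_obs)
    fill = (~observed) & (last_obs >= 0) & (idx - last_obs <= max_gap)
    values[fill] = values[last_obs[fill]]
    quality[fill] = LOCF_FILLED
    source[fill] = last_obs[fill]
    quality[np.isnan(values) & (quality != MISSING)] = MISSING
    return MinuteGrid(grid.channel, grid.start, values, quality, source)
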