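"""Single-lead ECG segment quality assessment.

Heart rate on the ward monitor is derived from 10-s single-lead ECG
segments digitized at 1000 samples/s, one segment per monitored minute.
A segment is usable only if its beats are mutually consistent: QRS
complexes are detected, an average-beat template is built from them, each
beat is correlated against the template, and the segment is rejected as
artefact when the worst beat correlates poorly (the minimum per-beat
correlation falls below a configurable threshold, default 0.8).  Accepted
segments yield the heart rate ``60 * (n_beats - 1) / span_seconds`` from
the span between the first and last R peak.

The QRS detector is a standard derivative-energy peak picker with a 200-ms
refractory period; the segment-quality logic, not the detector, is what
matters here, and the detector is deliberately simple.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy.signal import find_peaks


@dataclass(frozen=True)
class EcgSegment:
    """One 10-s ECG excerpt attached to a monitored minute."""

    minute_index: int
    samples: np.ndarray
    sampling_rate: int = 1000

    def __post_init__(self):
        object.__setattr__(self, "samples", np.asarray(self.samples, dtype=float))
        expected = 10 * self.sampling_rate
        if len(self.samples) != expected:
            raise ValueError(
                f"segment must hold 10 s at {self.sampling_rate}/s "
                f"({expected} samples), got {len(self.samples)}"
            )


@dataclass
class EcgAssessment:
    quality: str  # "accepted" | "rejected"
    hr: Optional[float] = None  # beats/min, accepted segments only
    reason: Optional[str] = None
    peak_indices: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=int))
    beat_correlations: np.ndarray = field(default_factory=lambda: np.empty(0))

    @property
    def accepted(self) -> bool:
        return self.quality == "accepted"


REFRACTORY_MS = 200
BEAT_HALF_WINDOW_MS = 120


def detect_qrs(samples: np.ndarray, sampling_rate: int = 1000) -> np.ndarray:
    """Locate R peaks with a derivative-energy detector.

    The squared first difference is smoothed over a 120-ms window; peaks of
    the smoothed energy at least 200 ms apart and above a quarter of the
    maximum energy are candidate beats, each refined to the largest absolute
    deflection of the centred signal within +/-60 ms.
    """
    x = samples - np.mean(samples)
    if len(x) < 2:
        return np.empty(0, dtype=int)
    # 25-ms moving-average pre-smoothing: attenuates broadband noise while
    # leaving the ~100-ms QRS deflection essentially intact
    w_smooth = max(1, int(0.025 * sampling_rate))
    xs = np.convolve(x, np.ones(w_smooth) / w_smooth, mode="same")
    energy = np.diff(xs) ** 2
    w = max(1, int(0.120 * sampling_rate))
    smooth = np.convolve(energy, np.ones(w) / w, mode="same")
    peak_height = 0.25 * smooth.max()
    if peak_height <= 0:
        return np.empty(0, dtype=int)
    refractory = int(REFRACTORY_MS * sampling_rate / 1000)
    locs, _ = find_peaks(smooth, height=peak_height, distance=refractory)
    # refine to the R deflection near each energy peak
    half = int(0.060 * sampling_rate)
    refined = []
    for loc in locs:
        a, b = max(0, loc - half), min(len(x), loc + half + 1)
        refined.append(a + int(np.argmax(np.abs(x[a:b]))))
    refined = np.unique(refined)
    # drop refinements collapsing inside the refractory period
    keep = []
    for r in refined:
        if not keep or r - keep[-1] >= refractory:
            keep.append(r)
    return np.asarray(keep, dtype=int)


def _beat_windows(x: np.ndarray, peaks: np.ndarray, half: int):
    """Full-width beat windows (peaks too close to the edges are dropped)."""
    kept, windows = [], []
    for p in peaks:
        if p - half >= 0 and p + half < len(x):
            kept.append(p)
            windows.append(x[p - half : p + half + 1])
    return np.asarray(kept, dtype=int), np.asarray(windows)


def _safe_corr(a: np.ndarray, b: np.ndarray) -> float:
    sa, sb = np.std(a), np.std(b)
    if sa == 0 or sb == 0:
        return 0.0
    return float(np.corrcoef(a, b)[0, 1])


def assess_ecg_segment(
    segment: EcgSegment, correlation_threshold: float = 0.8
) -> EcgAssessment:
    """Judge a segment's signal quality and derive its heart rate.

    Each detected beat is correlated with the average-beat template of the
    segment; the segment is accepted iff the minimum per-beat correlation
    reaches ``correlation_threshold``, in which case the heart rate over the
    segment is returned.
    """
    if not 0 < correlation_threshold < 1:
        raise ValueError("correlation_threshold must lie in (0, 1)")
    fs = segment.sampling_rate
    x = segment.samples - np.mean(segment.samples)
    peaks = detect_qrs(segment.samples, fs)
    half = int(BEAT_HALF_WINDOW_MS * fs / 1000)
    peaks, windows = _beat_windows(x, peaks, half)
    if len(peaks) < 2:
        return EcgAssessment("rejected", reason="insufficient beats")

    template = windows.mean(axis=0)
    corr = np.array([_safe_corr(w, template) for w in windows])
    if corr.min() < correlation_threshold:
        return EcgAssessment(
            "rejected",
            reason="low template correlation",
            peak_indices=peaks,
            beat_correlations=corr,
        )
    span_s = (peaks[-1] - peaks[0]) / fs
    hr = 60.0 * (len(peaks) - 1) / span_s
    return EcgAssessment("accepted", hr=hr, peak_indices=peaks, beat_correlations=corr)


# ---------------------------------------------------------------------------
# synthetic segments (used by the simulator and the test-suite)
# ---------------------------------------------------------------------------

def qrs_template(sampling_rate: int = 1000) -> np.ndarray:
    """A stylised QRS-T beat shape (~400 ms) built from Gaussian bumps."""
    t = np.arange(int(0.400 * sampling_rate)) / sampling_rate
    def bump(center, width, amp):
        return amp * np.exp(-0.5 * ((t - center) / width) ** 2)
    beat = (
        bump(0.080, 0.010, -0.15)   # Q
        + bump(0.100, 0.012, 1.0)   # R
        + bump(0.120, 0.010, -0.25) # S
        + bump(0.280, 0.040, 0.25)  # T
    )
    return beat


def make_ecg_segment(
    hr_bpm: float,
    minute_index: int = 0,
    sampling_rate: int = 1000,
    noise_sd: float = 0.0,
    rng: Optional[np.random.Generator] = None,
) -> EcgSegment:
    """Tile the stylised beat at a fixed rate into a 10-s segment."""
    n = 10 * sampling_rate
    x = np.zeros(n)
    beat = qrs_template(sampling_rate)
    period = int(round(60.0 / hr_bpm * sampling_rate))
    start = int(0.2 * sampling_rate)
    for onset in range(start, n, period):
        seg = beat[: n - onset]
        x[onset : onset + len(seg)] += seg
    if noise_sd > 0:
        rng = rng or np.random.default_rng()
        x = x + rng.normal(0.0, noise_sd, size=n)
    return EcgSegment(minute_index=minute_index, samples=x, sampling_rate=sampling_rate)
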