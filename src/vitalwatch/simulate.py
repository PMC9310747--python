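"""Synthetic postoperative-cohort generator.

Emulates the monitoring design the analysis expects: per-minute heart and
respiratory rate, sub-minute pulse-oximetry, intermittent oscillometric
blood pressure on the 30-min-day / 60-min-night schedule, monitoring capped
at 96 h, and a first serious adverse event (SAE) drawn so that roughly 37 %
of patients have one, 38 % of those during monitoring, with SAE times
log-normal around a median of 4 days 15 h.

Each channel's signal is baseline + a 24-h circadian sinusoid (peak in the
afternoon) + lag-1 autoregressive noise, with between-patient baseline
variation; pulse oximetry additionally carries transient desaturation
events (smooth dips, so they never violate the 4 %/s artefact rule).
Device-removal gaps, out-of-schedule dropout and artefact contamination
(implausible spikes on HR/RR, step-like drops on SpO2 that do violate the
slope rule) are injected on top.  An optional pre-SAE physiologic shift
(step or ramp) is applied over a configurable window before the first SAE.

All randomness flows from one seed; each patient gets an index-derived
substream per purpose (SAE, one per channel, gaps, artefacts), so changing
e.g. the artefact rate leaves every other draw untouched.
"""

from __future__ import annotations

import importlib.resources
from typing import Dict, Literal, Optional, Sequence, Tuple

import numpy as np
import yaml
from pydantic import BaseModel, Field, model_validator
from scipy.signal import lfilter

from .cohort import PatientRecord
from .series import SampleSeries

_CH = ("HR", "RR", "SPO2", "SBP")


class CohortSimParams(BaseModel):
    """All knobs of the cohort simulator (defaults emulate the study design)."""

    n_patients: int = Field(491, ge=1)
    seed: int = 0
    sae_prevalence: float = Field(0.37, ge=0.0, le=1.0)
    fraction_sae_during: float = Field(0.38, ge=0.0, le=1.0)

    # monitoring window
    monitoring_hours: float = Field(79.0, gt=0.0, le=96.0)
    monitoring_jitter_hours: float = Field(0.0, ge=0.0)
    start_hour_range: Tuple[float, float] = (12.0, 20.0)
    base_date: str = "2022-03-01"

    # signal model
    baseline: Dict[str, float] = {"HR": 75.0, "RR": 16.0, "SPO2": 95.0, "SBP": 125.0}
    between_sd: Dict[str, float] = {"HR": 9.0, "RR": 2.5, "SPO2": 2.6, "SBP": 18.0}
    #: sparse between-patient phenotypes, e.g. postoperative atrial
    #: fibrillation (sustained tachycardia), opioid bradypnea relief or
    #: fever tachypnea, uncontrolled hypertension: list of
    #: (fraction, baseline shift) per channel
    mixture: Dict[str, list] = {
        "HR": [[0.04, 25.0], [0.02, -32.0]],
        "RR": [[0.06, 9.0]],
        "SBP": [[0.06, 40.0]],
    }
    circadian_amplitude: Dict[str, float] = {"HR": 6.0, "RR": 2.0, "SPO2": 1.2, "SBP": 6.0}
    acrophase_hour: float = 16.0
    ar_phi: Dict[str, float] = {"HR": 0.97, "RR": 0.95, "SPO2": 0.97}
    noise_sd: Dict[str, float] = {"HR": 6.5, "RR": 2.0, "SPO2": 2.5}
    sbp_noise_sd: float = 14.0
    spo2_interval_s: int = Field(10, ge=1, le=60)

    # transient desaturation events (pulse oximetry only)
    desat_rate_per_hour: float = 1.2
    desat_rate_dispersion: float = 0.6  # gamma shape for between-patient rates
    desat_depth_mean: float = 8.0  # % (exponential)
    desat_duration_mean_min: float = 4.0  # minutes (exponential)

    # missingness and artefacts
    gap_rate_per_hour: Dict[str, float] = {"HR": 0.08, "RR": 0.08, "SPO2": 0.12}
    gap_mean_minutes: Dict[str, float] = {"HR": 60.0, "RR": 60.0, "SPO2": 220.0}
    sbp_dropout: float = Field(0.45, ge=0.0, lt=1.0)
    artifact_rate: Dict[str, float] = {"HR": 0.005, "RR": 0.005, "SPO2": 0.005, "SBP": 0.0}

    # pre-SAE physiologic shift
    pre_sae_effect: Dict[str, float] = {}
    pre_sae_effect_hours: float = Field(6.0, gt=0.0)
    pre_sae_effect_shape: Literal["step", "ramp"] = "step"

    # first-SAE time model (hours since monitoring start)
    sae_lognormal_mu: float = 4.70953  # ln(111 h): median 4 d 15 h
    sae_lognormal_sigma: float = 0.98657  # matches IQR 2 d 3 h – 8 d 1 h
    sae_followup_hours: float = 720.0  # 30 days
    #: "lognormal" draws during-SAE times inside the monitoring window;
    #: "end_of_monitoring" pins them to monitoring end, making every
    #: exposure window identical (the null-calibration configuration)
    sae_time_mode: Literal["lognormal", "end_of_monitoring"] = "lognormal"

    # blood-pressure schedule (clock-anchored)
    bp_day_interval: int = 30
    bp_night_interval: int = 60
    day_start_minute: int = 7 * 60
    night_start_minute: int = 22 * 60

    @model_validator(mode="after")
    def _check(self) -> "CohortSimParams":
        lo, hi = self.start_hour_range
        if not (0 <= lo <= hi < 24):
            raise ValueError("start_hour_range must satisfy 0 <= lo <= hi < 24")
        return self


class _PatientRngs:
    """Lazy per-purpose random substreams for one patient.

    Every purpose (SAE draw, each channel, gaps, artefacts, desaturations,
    window) has a fixed child seed derived from (cohort seed, patient
    index), so switching one process off leaves every other draw unchanged.
    """

    _NAMES = ("sae", "HR", "RR", "SPO2", "SBP", "gaps", "artifacts", "desat", "window")

    def __init__(self, params: CohortSimParams, index: int):
        ss = np.random.SeedSequence(entropy=params.seed, spawn_key=(index,))
        self._children = dict(zip(self._NAMES, ss.spawn(len(self._NAMES))))
        self._cache: dict = {}

    def __getitem__(self, name: str) -> np.random.Generator:
        if name not in self._cache:
            self._cache[name] = np.random.default_rng(self._children[name])
        return self._cache[name]


def _patient_rngs(params: CohortSimParams, index: int) -> _PatientRngs:
    return _PatientRngs(params, index)


def _baseline_offset(rng, params: CohortSimParams, channel: str) -> float:
    """Between-patient offset: Gaussian spread plus sparse phenotype shifts."""
    off = rng.normal(0.0, params.between_sd[channel])
    u = rng.uniform()
    acc = 0.0
    for frac, shift in params.mixture.get(channel, []):
        acc += frac
        if u < acc:
            off += shift
            break
    return off


def _ar1(rng, n: int, phi: float, sd: float) -> np.ndarray:
    """Stationary AR(1) path of length n with marginal SD ``sd``."""
    if n == 0:
        return np.empty(0)
    if sd <= 0:
        return np.zeros(n)
    eps = rng.normal(0.0, sd * np.sqrt(1.0 - phi * phi), size=n)
    eps[0] = rng.normal(0.0, sd)
    return lfilter([1.0], [1.0, -phi], eps)


def _circadian(minutes_of_day: np.ndarray, amplitude: float, acrophase_hour: float) -> np.ndarray:
    return amplitude * np.cos(2 * np.pi * (minutes_of_day / 60.0 - acrophase_hour) / 24.0)


def _gap_mask(rng, n_minutes: int, rate_per_hour: float, mean_minutes: float) -> np.ndarray:
    """True = retained.  Gaps start at Poisson times, exponential lengths."""
    keep = np.ones(n_minutes, dtype=bool)
    if rate_per_hour <= 0 or n_minutes == 0:
        return keep
    n_gaps = rng.poisson(rate_per_hour * n_minutes / 60.0)
    for _ in range(n_gaps):
        start = rng.integers(0, n_minutes)
        length = max(1, int(round(rng.exponential(mean_minutes))))
        keep[start : start + length] = False
    return keep


def _effect_profile(
    offsets_min: np.ndarray, sae_offset_min: float, effect_min: float, shape: str
) -> np.ndarray:
    """Weight in [0,1] of the pre-SAE shift at each time offset (minutes)."""
    w = np.zeros(len(offsets_min))
    lo = sae_offset_min - effect_min
    inside = (offsets_min >= lo) & (offsets_min < sae_offset_min)
    if shape == "step":
        w[inside] = 1.0
    else:  # ramp
        w[inside] = (offsets_min[inside] - lo) / effect_min
    return w


def bp_schedule_offsets(
    start_minute_of_day: int,
    n_minutes: int,
    day_interval: int = 30,
    night_interval: int = 60,
    day_start_minute: int = 420,
    night_start_minute: int = 1320,
) -> np.ndarray:
    """Minute offsets (from window start) of scheduled BP measurements.

    Measurements are clock-anchored: every ``day_interval`` minutes on the
    day marks (07:00, 07:30, ...) and every ``night_interval`` minutes on
    the night marks (22:00, 23:00, ...).  Over one full day this yields 39
    measurements (30 by day, 9 by night) with the defaults.
    """
    k = np.arange(n_minutes)
    mod = (start_minute_of_day + k) % 1440
    is_day = (mod >= day_start_minute) & (mod < night_start_minute)
    scheduled = np.where(is_day, mod % day_interval == 0, mod % night_interval == 0)
    return k[scheduled]


_SAE_DIST_CACHE: dict = {}


def _sae_dist(mu: float, sigma: float):
    key = (mu, sigma)
    if key not in _SAE_DIST_CACHE:
        from scipy.stats import lognorm

        _SAE_DIST_CACHE[key] = lognorm(s=sigma, scale=np.exp(mu))
    return _SAE_DIST_CACHE[key]


def _draw_sae_hours(rng, params: CohortSimParams, mon_hours: float) -> Optional[float]:
    """First-SAE time in hours since monitoring start, or None."""
    if rng.uniform() >= params.sae_prevalence:
        return None
    during = rng.uniform() < params.fraction_sae_during
    if during and params.sae_time_mode == "end_of_monitoring":
        return mon_hours
    lo, hi = (0.0, mon_hours) if during else (mon_hours, params.sae_followup_hours)
    # inverse-CDF sampling of the truncated log-normal
    dist = _sae_dist(params.sae_lognormal_mu, params.sae_lognormal_sigma)
    a, b = dist.cdf(lo), dist.cdf(hi)
    if b <= a:  # degenerate truncation; fall back to uniform on the interval
        return float(rng.uniform(lo, hi))
    t = float(dist.ppf(a + rng.uniform() * (b - a)))
    return min(max(t, lo + 1e-6), hi)


def generate_patient(params: CohortSimParams, patient_index: int) -> PatientRecord:
    """Simulate one patient's streams, monitoring window and first SAE."""
    rngs = _patient_rngs(params, patient_index)
    rw = rngs["window"]

    mon_hours = params.monitoring_hours
    if params.monitoring_jitter_hours > 0:
        mon_hours += rw.uniform(-1.0, 1.0) * params.monitoring_jitter_hours
    mon_hours = float(min(max(mon_hours, 1.0), 96.0))
    n_minutes = int(round(mon_hours * 60))

    lo, hi = params.start_hour_range
    start_hour = rw.uniform(lo, hi)
    start = (
        np.datetime64(params.base_date, "s")
        + np.timedelta64(patient_index, "D").astype("timedelta64[s]")
        + np.timedelta64(int(start_hour * 60) * 60, "s")
    )
    end = start + np.timedelta64(n_minutes * 60, "s")
    start_mod = int((start - start.astype("datetime64[D]")) / np.timedelta64(1, "s")) // 60

    sae_hours = _draw_sae_hours(rngs["sae"], params, mon_hours)
    sae_time = None
    sae_offset_min = np.inf
    if sae_hours is not None:
        sae_offset_min = sae_hours * 60.0
        sae_time = start + np.timedelta64(int(round(sae_hours * 3600)), "s")

    effect_min = params.pre_sae_effect_hours * 60.0
    ra = rngs["artifacts"]
    rg = rngs["gaps"]
    series: dict[str, SampleSeries] = {}

    # --- per-minute channels: HR and RR ---------------------------------
    k = np.arange(n_minutes)
    mod = (start_mod + k) % 1440
    for ch in ("HR", "RR"):
        base = params.baseline[ch] + _baseline_offset(rngs[ch], params, ch)
        x = base + _circadian(mod.astype(float), params.circadian_amplitude[ch],
                              params.acrophase_hour)
        x = x + _ar1(rngs[ch], n_minutes, params.ar_phi[ch], params.noise_sd[ch])
        if ch in params.pre_sae_effect and np.isfinite(sae_offset_min):
            x = x + params.pre_sae_effect[ch] * _effect_profile(
                k.astype(float), sae_offset_min, effect_min, params.pre_sae_effect_shape
            )
        keep = _gap_mask(rg, n_minutes, params.gap_rate_per_hour.get(ch, 0.0),
                         params.gap_mean_minutes.get(ch, 60.0))
        rate = params.artifact_rate.get(ch, 0.0)
        if rate > 0:
            spike = ra.uniform(size=n_minutes) < rate
            x = np.where(spike, 330.0 if ch == "HR" else 95.0, x)  # implausible
        series[ch] = SampleSeries(ch, start + (k[keep] * 60).astype("timedelta64[s]"),
                                  x[keep])

    # --- pulse oximetry at sub-minute cadence ---------------------------
    dt = params.spo2_interval_s
    n_s = n_minutes * 60 // dt
    ks = np.arange(n_s)
    offs_min = ks * dt / 60.0
    mod_s = (start_mod + offs_min) % 1440
    rs = rngs["SPO2"]
    base = params.baseline["SPO2"] + _baseline_offset(rs, params, "SPO2")
    phi_s = params.ar_phi["SPO2"] ** (dt / 60.0)
    x = base + _circadian(mod_s, params.circadian_amplitude["SPO2"], params.acrophase_hour)
    x = x + _ar1(rs, n_s, phi_s, params.noise_sd["SPO2"])
    # transient desaturation events: smooth trapezoid dips
    rd = rngs["desat"]
    if params.desat_rate_per_hour > 0:
        shape = params.desat_rate_dispersion
        rel_rate = rd.gamma(shape, 1.0 / shape) if shape > 0 else 1.0
        n_ev = rd.poisson(params.desat_rate_per_hour * rel_rate * mon_hours)
        for _ in range(n_ev):
            center = rd.uniform(0, n_minutes)
            depth = rd.exponential(params.desat_depth_mean)
            dur_min = max(0.5, rd.exponential(params.desat_duration_mean_min))
            half = dur_min / 2.0
            ramp = max(half / 2.0, depth / 4.0 / 60.0 * 2)  # keeps slope << 4 %/s
            d = np.abs(offs_min - center)
            prof = np.clip((half - d) / ramp, 0.0, 1.0)
            x = x - depth * prof
    if "SPO2" in params.pre_sae_effect and np.isfinite(sae_offset_min):
        x = x + params.pre_sae_effect["SPO2"] * _effect_profile(
            offs_min, sae_offset_min, effect_min, params.pre_sae_effect_shape
        )
    x = np.clip(x, 41.0, 100.0)
    rate = params.artifact_rate.get("SPO2", 0.0)
    if rate > 0:
        spike = ra.uniform(size=n_s) < rate
        # step drop steep enough to violate the 4 %/s rule at this cadence;
        # skipped where the signal is already too low for a full-depth step
        # (and on the first sample, which has no slope baseline)
        drop = 5.0 * dt + 5.0
        spike &= x - drop >= 41.0
        if len(spike):
            spike[0] = False
        x = np.where(spike, x - drop, x)
    keep_min = _gap_mask(rg, n_minutes, params.gap_rate_per_hour.get("SPO2", 0.0),
                         params.gap_mean_minutes.get("SPO2", 60.0))
    keep = keep_min[(ks * dt // 60).astype(int)]
    series["SPO2"] = SampleSeries(
        "SPO2", start + (ks[keep] * dt).astype("timedelta64[s]"), x[keep]
    )

    # --- intermittent oscillometric blood pressure ----------------------
    offs = bp_schedule_offsets(start_mod, n_minutes, params.bp_day_interval,
                               params.bp_night_interval, params.day_start_minute,
                               params.night_start_minute)
    rb = rngs["SBP"]
    base = params.baseline["SBP"] + _baseline_offset(rb, params, "SBP")
    mod_b = (start_mod + offs) % 1440
    xb = base + _circadian(mod_b.astype(float), params.circadian_amplitude["SBP"],
                           params.acrophase_hour)
    xb = xb + rb.normal(0.0, params.sbp_noise_sd, size=len(offs))
    if "SBP" in params.pre_sae_effect and np.isfinite(sae_offset_min):
        xb = xb + params.pre_sae_effect["SBP"] * _effect_profile(
            offs.astype(float), sae_offset_min, effect_min, params.pre_sae_effect_shape
        )
    if params.sbp_dropout > 0:
        keep_b = rb.uniform(size=len(offs)) >= params.sbp_dropout
    else:
        keep_b = np.ones(len(offs), dtype=bool)
    series["SBP"] = SampleSeries(
        "SBP", start + (offs[keep_b] * 60).astype("timedelta64[s]"), xb[keep_b]
    )

    return PatientRecord(
        patient_id=f"P{patient_index:04d}",
        monitoring_start=start,
        monitoring_end=end,
        series=series,
        first_sae_time=sae_time,
    )


def generate_cohort(params: CohortSimParams) -> list[PatientRecord]:
    """Simulate the full cohort (patients are independent substreams)."""
    return [generate_patient(params, i) for i in range(params.n_patients)]


# ---------------------------------------------------------------------------
# planting explicit episodes (for exact-recovery checks)
# ---------------------------------------------------------------------------

def plant_interval(
    record: PatientRecord, channel: str, start_minute: int, duration: int, value: float
) -> None:
    """Overwrite a channel's samples inside [start, start+duration) minutes.

    Used with a noise-free, artefact-free cohort to plant abnormality
    episodes whose exact recovery (count, onset, duration) the detection
    pipeline is then held to.
    """
    s = record.series[channel]
    offs_min = (s.times - record.monitoring_start) / np.timedelta64(60, "s")
    inside = (offs_min >= start_minute) & (offs_min < start_minute + duration)
    s.values[inside] = value


def quiet_params(**overrides) -> CohortSimParams:
    """Deterministic-skeleton parameters: no noise, gaps, artefacts or desats."""
    base = dict(
        noise_sd={"HR": 0.0, "RR": 0.0, "SPO2": 0.0},
        sbp_noise_sd=0.0,
        between_sd={"HR": 0.0, "RR": 0.0, "SPO2": 0.0, "SBP": 0.0},
        gap_rate_per_hour={"HR": 0.0, "RR": 0.0, "SPO2": 0.0},
        artifact_rate={"HR": 0.0, "RR": 0.0, "SPO2": 0.0, "SBP": 0.0},
        desat_rate_per_hour=0.0,
        sbp_dropout=0.0,
    )
    base.update(overrides)
    return CohortSimParams(**base)


# ---------------------------------------------------------------------------
# scenario presets
# ---------------------------------------------------------------------------

def load_scenario(name_or_path, **overrides) -> CohortSimParams:
    """Load a scenario preset by name (``null``, ``tachycardia-effect``,
    ``hypotension-effect``, ``paper-like``) or from a YAML file path."""
    text = None
    candidate = str(name_or_path)
    pkg_files = importlib.resources.files("vitalwatch") / "scenarios"
    builtin = pkg_files / f"{candidate}.yaml"
    if builtin.is_file():
        text = builtin.read_text()
    else:
        with open(candidate) as fh:
            text = fh.read()
    data = yaml.safe_load(text) or {}
    data.update(overrides)
    return CohortSimParams.model_validate(data)
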