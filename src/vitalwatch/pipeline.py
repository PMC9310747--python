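"""End-to-end cohort analysis: preprocessing, episode detection, grouping,
24-h normalization, day/night stratification and group comparisons.

:func:`analyze_patient` turns one patient's raw streams into per-tier
outcomes inside that patient's exposure window; :func:`analyze_cohort`
aggregates a cohort into frequency tables (patients with >= 1 normalized
episode per tier, chi-square across the three SAE groups) and duration
summaries (median/IQR of normalized abnormal minutes, Kruskal-Wallis),
overall and per day/night stratum.  :func:`run_pipeline` is the file-based
orchestration used by the command line.
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Optional, Sequence

import numpy as np
import pandas as pd

from . import __version__
from .cohort import (
    ExposureWindow,
    GroupLabel,
    GROUP_ORDER,
    PatientRecord,
    assign_group,
    build_contingency,
    day_mask,
    exposure_window,
    has_abnormality,
    stratum_normalization_factor,
)
from .config import AnalysisConfig, CONTINUOUS_CHANNELS
from .episodes import detect_bp_episodes, detect_channel_episodes
from .preprocess import apply_plausibility_gate, filter_spo2_artifacts, locf_fill, to_minute_grid
from .series import OBSERVED, MinuteGrid, SampleSeries
from .stats import TestResult, chi_square_test, kruskal_wallis_test, median_iqr
from .tiers import DEFAULT_TIERS, ThresholdTier

STRATA = ("day", "night")


@dataclass
class StratumOutcome:
    minutes_in_window: int
    n_episodes: int
    condition_minutes: float
    normalized_count: float
    normalized_minutes: float

    @property
    def has_abnormality(self) -> bool:
        return has_abnormality(self.normalized_count)


@dataclass
class TierOutcome:
    tier: ThresholdTier
    covered: bool
    n_episodes: int = 0
    condition_minutes: float = 0.0
    normalized_count: float = 0.0
    normalized_minutes: float = 0.0
    episodes: list = field(default_factory=list)
    by_stratum: Dict[str, StratumOutcome] = field(default_factory=dict)

    @property
    def has_abnormality(self) -> bool:
        return has_abnormality(self.normalized_count)


@dataclass
class PatientAnalysis:
    patient_id: str
    group: GroupLabel
    window: ExposureWindow
    tiers: Dict[str, TierOutcome]
    total_abnormal_minutes: float
    total_abnormal_normalized: float
    total_by_stratum: Dict[str, float]  # normalized abnormal minutes per stratum
    monitored_minutes: Dict[str, int]  # observed minutes per channel in window


def preprocess_channel(
    record: PatientRecord,
    channel: str,
    config: AnalysisConfig,
    window: tuple,
) -> MinuteGrid:
    """Gate, filter, minute-average and LOCF-fill one channel's stream."""
    series = record.series.get(channel)
    if series is None:
        series = SampleSeries(channel, np.empty(0, dtype="datetime64[s]"), np.empty(0))
    if config.plausibility_gate:
        series = apply_plausibility_gate(series)
    if channel == "SPO2":
        series = filter_spo2_artifacts(series, config.spo2_slope_limit)
    grid = to_minute_grid(series, window)
    if channel in config.locf_channels:
        grid = locf_fill(grid, config.locf_max_minutes)
    return grid


def _mildest_tiers(tiers: Sequence[ThresholdTier]) -> list[ThresholdTier]:
    """Least-severe continuous tier per (channel, direction).

    The union of these conditions defines a minute as "abnormal" for the
    total-duration summary, without double counting nested severities.
    """
    best: dict = {}
    for t in tiers:
        if t.is_bp:
            continue
        key = (t.channel, t.direction)
        cur = best.get(key)
        if cur is None:
            best[key] = t
        elif t.direction == "below" and t.threshold > cur.threshold:
            best[key] = t
        elif t.direction == "above" and t.threshold < cur.threshold:
            best[key] = t
    return list(best.values())


def analyze_patient(
    record: PatientRecord,
    config: Optional[AnalysisConfig] = None,
    tiers: Sequence[ThresholdTier] = DEFAULT_TIERS,
) -> PatientAnalysis:
    """Run the full single-patient analysis inside the exposure window.

    For a SAE-during patient nothing after the first SAE enters any
    computation: the minute grids and the blood-pressure sequence are both
    cut at the window end before detection.
    """
    config = config or AnalysisConfig()
    cap = np.timedelta64(config.max_monitoring_hours * 3600, "s")
    mon_end = min(record.monitoring_end, record.monitoring_start + cap)
    capped = PatientRecord(
        patient_id=record.patient_id,
        monitoring_start=record.monitoring_start,
        monitoring_end=mon_end,
        series=record.series,
        first_sae_time=record.first_sae_time,
    )
    group = assign_group(capped)

    mon_window = (capped.monitoring_start, capped.monitoring_end)
    grids = {ch: preprocess_channel(capped, ch, config, mon_window)
             for ch in ("HR", "RR", "SPO2", "SBP")}

    win = exposure_window(capped, group)
    w0 = int(round((win.start - capped.monitoring_start) / np.timedelta64(60, "s")))
    w1 = int(round((win.end - capped.monitoring_start) / np.timedelta64(60, "s")))
    slices = {ch: g.slice(w0, w1) for ch, g in grids.items()}
    n_win = w1 - w0

    observed_any = np.zeros(n_win, dtype=bool)
    monitored = {}
    for ch, sl in slices.items():
        obs = sl.quality == OBSERVED
        monitored[ch] = int(obs.sum())
        observed_any |= obs
    if config.coverage_based_normalization:
        win = exposure_window(capped, group,
                              monitored_minutes=float(observed_any.sum()),
                              coverage_based=True)
    if config.min_monitoring_minutes and win.length_minutes < config.min_monitoring_minutes:
        raise ValueError(
            f"{record.patient_id}: exposure window shorter than the configured floor"
        )

    dmask = day_mask(win.start, n_win, config)
    strat_minutes = {"day": int(dmask.sum()), "night": int(n_win - dmask.sum())}
    strat_factor = {
        s: (stratum_normalization_factor(m, s, config) if m > 0 else np.nan)
        for s, m in strat_minutes.items()
    }

    # SBP measurement sequence cut to the window (retained samples only)
    sbp = capped.series.get("SBP")
    if sbp is not None:
        if config.plausibility_gate:
            sbp = apply_plausibility_gate(sbp)
        inside = (sbp.times >= win.start) & (sbp.times <= win.end)
        sbp = SampleSeries("SBP", sbp.times[inside], sbp.values[inside],
                           sbp.quality[inside])
    else:
        sbp = SampleSeries("SBP", np.empty(0, dtype="datetime64[s]"), np.empty(0))

    sbp_kept = sbp.retained_only()
    factor = win.normalization_factor
    d0 = config.day_start.hour * 60 + config.day_start.minute
    n0 = config.night_start.hour * 60 + config.night_start.minute
    outcomes: Dict[str, TierOutcome] = {}
    with np.errstate(invalid="ignore"):
        for tier in tiers:
            if tier.is_bp:
                eps = detect_bp_episodes(sbp_kept, tier)
                covered = len(sbp_kept) > 0
                cond = tier.condition(slices["SBP"].values)
                ep_records = [{
                    "start": sbp_kept.times[e.start], "end": sbp_kept.times[e.end],
                    "duration_min": e.duration, "n_merged": e.n_merged,
                } for e in eps]
            else:
                sl = slices[tier.channel]
                eps = detect_channel_episodes(sl, tier, config.merge_gap_minutes,
                                              config.persistence_mode)
                covered = monitored[tier.channel] > 0
                cond = tier.condition(sl.values)
                ep_records = [{
                    "start": win.start + np.timedelta64(60 * e.start, "s"),
                    "end": win.start + np.timedelta64(60 * (e.end + 1), "s"),
                    "duration_min": e.duration, "n_merged": e.n_merged,
                } for e in eps]
            cond_min = float(cond.sum())
            day_min = float((cond & dmask).sum())
            cond_by_stratum = {"day": day_min, "night": cond_min - day_min}

            out = TierOutcome(
                tier=tier, covered=covered, n_episodes=len(eps),
                condition_minutes=cond_min,
                normalized_count=len(eps) * factor,
                normalized_minutes=cond_min * factor,
                episodes=ep_records,
            )
            # day/night stratification: episodes by onset clock time,
            # abnormal minutes split minute-by-minute
            starts_mod = np.array([_minute_of_day(r["start"]) for r in ep_records],
                                  dtype=float)
            ep_is_day = (starts_mod >= d0) & (starts_mod < n0)
            for stratum in STRATA:
                m = strat_minutes[stratum]
                f = strat_factor[stratum]
                n_ep_s = int(ep_is_day.sum() if stratum == "day"
                             else len(ep_records) - ep_is_day.sum())
                cm = cond_by_stratum[stratum]
                out.by_stratum[stratum] = StratumOutcome(
                    minutes_in_window=m, n_episodes=n_ep_s, condition_minutes=cm,
                    normalized_count=n_ep_s * f if m > 0 else np.nan,
                    normalized_minutes=cm * f if m > 0 else np.nan,
                )
            outcomes[tier.label] = out

        # total abnormal duration: union of the mildest condition per channel
        union = np.zeros(n_win, dtype=bool)
        for t in _mildest_tiers(tiers):
            union |= t.condition(slices[t.channel].values)
    total_min = float(union.sum())
    total_strat = {}
    for stratum in STRATA:
        mask = dmask if stratum == "day" else ~dmask
        m = strat_minutes[stratum]
        total_strat[stratum] = (
            float((union & mask).sum()) * strat_factor[stratum] if m > 0 else np.nan
        )

    return PatientAnalysis(
        patient_id=record.patient_id,
        group=group,
        window=win,
        tiers=outcomes,
        total_abnormal_minutes=total_min,
        total_abnormal_normalized=total_min * factor,
        total_by_stratum=total_strat,
        monitored_minutes=monitored,
    )


def _minute_of_day(ts: np.datetime64) -> int:
    ts = np.datetime64(ts, "s")
    return int((ts - ts.astype("datetime64[D]")) / np.timedelta64(1, "s")) // 60


# ---------------------------------------------------------------------------
# cohort-level aggregation
# ---------------------------------------------------------------------------

@dataclass
class CohortResult:
    patients: list
    config: AnalysisConfig
    tiers: Sequence[ThresholdTier]

    def group_sizes(self) -> Dict[GroupLabel, int]:
        sizes = {g: 0 for g in GROUP_ORDER}
        for p in self.patients:
            sizes[p.group] += 1
        return sizes

    def _by_group(self):
        by = {g: [] for g in GROUP_ORDER}
        for p in self.patients:
            by[p.group].append(p)
        return {g: v for g, v in by.items() if v}

    def tier_contingency(self, tier_label: str, stratum: Optional[str] = None):
        """2 x k table of patients with/without the abnormality, plus the
        number excluded for having no monitored minutes on that channel."""
        flags = {}
        excluded = 0
        for g, patients in self._by_group().items():
            fl = []
            for p in patients:
                out = p.tiers[tier_label]
                if not out.covered:
                    excluded += 1
                    continue
                if stratum is None:
                    fl.append(out.has_abnormality)
                else:
                    so = out.by_stratum[stratum]
                    if so.minutes_in_window <= 0:
                        excluded += 1
                        continue
                    fl.append(so.has_abnormality)
            flags[g] = fl
        table = build_contingency(flags)
        return table, excluded

    def frequency_table(self, stratum: Optional[str] = None) -> pd.DataFrame:
        """Per-tier counts (%) of patients with >= 1 normalized episode per
        group, with the chi-square comparison across groups."""
        rows = []
        for tier in self.tiers:
            label = tier.label
            try:
                table, excluded = self.tier_contingency(label, stratum)
            except ValueError:
                continue
            row = {"tier": label, "channel": tier.channel,
                   "direction": tier.direction, "threshold": tier.threshold,
                   "n_excluded": excluded}
            for g, w, n in zip(table.groups, table.with_abnormality, table.group_sizes):
                row[f"{g.value}_with"] = int(w)
                row[f"{g.value}_n"] = int(n)
                row[f"{g.value}_pct"] = round(100.0 * w / n, 1)
            try:
                res = chi_square_test(table.to_array())
                row["chi2"] = res.statistic
                row["p_value"] = res.p_value
            except ValueError:
                row["chi2"] = np.nan
                row["p_value"] = np.nan
            rows.append(row)
        return pd.DataFrame(rows).sort_values("tier").reset_index(drop=True)

    def duration_values(self, tier_label: Optional[str] = None,
                        stratum: Optional[str] = None) -> Dict[GroupLabel, np.ndarray]:
        """Per-group normalized abnormal minutes (total if no tier given)."""
        vals = {}
        for g, patients in self._by_group().items():
            v = []
            for p in patients:
                if tier_label is None:
                    x = (p.total_abnormal_normalized if stratum is None
                         else p.total_by_stratum[stratum])
                else:
                    out = p.tiers[tier_label]
                    if not out.covered:
                        continue
                    x = (out.normalized_minutes if stratum is None
                         else out.by_stratum[stratum].normalized_minutes)
                if x is not None and not np.isnan(x):
                    v.append(float(x))
            vals[g] = np.asarray(v)
        return vals

    def durations_table(self, stratum: Optional[str] = None) -> pd.DataFrame:
        """Median (IQR) normalized abnormal minutes per tier and group, with
        the Kruskal-Wallis comparison; the ``ANY`` row is the union across
        channels at the mildest thresholds."""
        rows = []
        labels = [None] + [t.label for t in self.tiers if not t.is_bp]
        for label in labels:
            vals = self.duration_values(label, stratum)
            groups = [g for g in GROUP_ORDER if g in vals and len(vals[g])]
            if len(groups) < 2:
                continue
            row = {"tier": label or "ANY"}
            for g in groups:
                med, q1, q3 = median_iqr(vals[g])
                row[f"{g.value}_median"] = med
                row[f"{g.value}_q1"] = q1
                row[f"{g.value}_q3"] = q3
                row[f"{g.value}_n"] = len(vals[g])
            res = kruskal_wallis_test([vals[g] for g in groups])
            row["kw_statistic"] = res.statistic
            row["p_value"] = res.p_value
            rows.append(row)
        return pd.DataFrame(rows).sort_values("tier").reset_index(drop=True)

    def episodes_frame(self) -> pd.DataFrame:
        rows = []
        for p in self.patients:
            for label, out in p.tiers.items():
                for e in out.episodes:
                    rows.append({
                        "patient_id": p.patient_id,
                        "channel": out.tier.channel,
                        "threshold": out.tier.threshold,
                        "direction": out.tier.direction,
                        "start": np.datetime_as_string(np.datetime64(e["start"], "s")),
                        "end": np.datetime_as_string(np.datetime64(e["end"], "s")),
                        "duration_min": round(float(e["duration_min"]), 3),
                        "n_merged": int(e["n_merged"]),
                    })
        df = pd.DataFrame(rows, columns=["patient_id", "channel", "threshold",
                                         "direction", "start", "end",
                                         "duration_min", "n_merged"])
        return df.sort_values(["patient_id", "channel", "threshold", "start"]
                              ).reset_index(drop=True)


def analyze_cohort(
    records: Sequence[PatientRecord],
    config: Optional[AnalysisConfig] = None,
    tiers: Sequence[ThresholdTier] = DEFAULT_TIERS,
) -> CohortResult:
    config = config or AnalysisConfig()
    patients = [analyze_patient(r, config, tiers) for r in records]
    return CohortResult(patients=patients, config=config, tiers=tiers)


# ---------------------------------------------------------------------------
# file-based orchestration
# ---------------------------------------------------------------------------

@dataclass
class RunManifest:
    config: dict
    input_digests: Dict[str, str]
    versions: Dict[str, str]
    outputs: Dict[str, str]
    elapsed_s: float
    seed: Optional[int] = None

    def to_json(self) -> str:
        return json.dumps(self.__dict__, indent=2, sort_keys=True)


def _digest(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def run_pipeline(
    streams_path,
    events_path,
    out_dir,
    config: Optional[AnalysisConfig] = None,
    config_path=None,
    tiers: Sequence[ThresholdTier] = DEFAULT_TIERS,
) -> RunManifest:
    """Read streams + events CSVs, analyse the cohort, write all outputs.

    Outputs (all under ``out_dir``): ``episodes.csv``, ``frequency.csv``,
    ``durations.csv``, day/night variants of both, ``stats.json`` and
    ``manifest.json``.  Identical inputs produce byte-identical tables.
    """
    from .io import read_events, read_streams

    t0 = time.time()
    if config is None:
        config = AnalysisConfig.from_file(config_path) if config_path else AnalysisConfig()
    events = read_events(events_path)
    streams = read_streams(streams_path)

    unknown = sorted(set(streams) - set(events))
    if unknown:
        raise ValueError(f"patients present in streams but absent from events: {unknown}")
    if not streams:
        raise ValueError("empty streams file")

    records = []
    for pid, meta in events.items():
        records.append(PatientRecord(
            patient_id=pid,
            monitoring_start=meta["monitoring_start"],
            monitoring_end=meta["monitoring_end"],
            series=streams.get(pid, {}),
            first_sae_time=meta["first_sae_time"],
        ))
    records.sort(key=lambda r: r.patient_id)
    result = analyze_cohort(records, config, tiers)

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    outputs = {}

    def _write(name: str, df: pd.DataFrame):
        path = out_dir / name
        df.to_csv(path, index=False, float_format="%.6g")
        outputs[name] = str(path)

    _write("episodes.csv", result.episodes_frame())
    _write("frequency.csv", result.frequency_table())
    _write("durations.csv", result.durations_table())
    for stratum in STRATA:
        _write(f"frequency_{stratum}.csv", result.frequency_table(stratum))
        _write(f"durations_{stratum}.csv", result.durations_table(stratum))

    sizes = result.group_sizes()
    stats = {
        "n_patients": len(records),
        "group_sizes": {g.value: int(n) for g, n in sizes.items()},
    }
    freq = result.frequency_table()
    stats["chi_square_p"] = {r["tier"]: (None if pd.isna(r["p_value"]) else r["p_value"])
                             for _, r in freq.iterrows()}
    dur = result.durations_table()
    stats["kruskal_wallis_p"] = {r["tier"]: r["p_value"] for _, r in dur.iterrows()}
    (out_dir / "stats.json").write_text(json.dumps(stats, indent=2, sort_keys=True))
    outputs["stats.json"] = str(out_dir / "stats.json")

    import scipy
    manifest = RunManifest(
        config=json.loads(config.model_dump_json()),
        input_digests={"streams": _digest(streams_path), "events": _digest(events_path)},
        versions={"vitalwatch": __version__, "numpy": np.__version__,
                  "pandas": pd.__version__, "scipy": scipy.__version__},
        outputs=outputs,
        elapsed_s=round(time.time() - t0, 3),
    )
    (out_dir / "manifest.json").write_text(manifest.to_json())
    return manifest
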