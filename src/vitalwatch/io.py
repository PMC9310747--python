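"""CSV input/output.

Two plain-text dialects tie the simulator and the analysis together:

* streams CSV — ``patient_id, timestamp (ISO 8601), channel, value``, one
  row per raw sample;
* events CSV — ``patient_id, monitoring_start, monitoring_end,
  first_sae_time`` (empty ``first_sae_time`` means no SAE).

An optional ECG directory holds one plain-numeric-text waveform file per
patient-minute (``<patient_id>_<minute_index>.txt``, 10 000 rows at
1000 samples/s); when supplied, per-minute heart rate is derived from the
accepted segments instead of being read from the streams file.
"""

from __future__ import annotations

import re
from pathlib import Path
from typing import Dict

import numpy as np
import pandas as pd

from .cohort import PatientRecord
from .config import CHANNELS, AnalysisConfig
from .ecg import EcgSegment, assess_ecg_segment
from .series import SampleSeries


def read_streams(path) -> Dict[str, Dict[str, SampleSeries]]:
    """Read a streams CSV into per-patient, per-channel sample series."""
    df = pd.read_csv(path, dtype={"patient_id": str, "channel": str})
    required = {"patient_id", "timestamp", "channel", "value"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"streams file lacks columns: {sorted(missing)}")
    bad = ~df["channel"].isin(CHANNELS)
    if bad.any():
        i = int(np.flatnonzero(bad.to_numpy())[0])
        raise ValueError(
            f"unknown channel {df['channel'].iloc[i]!r} in streams row {i + 2} "
            f"(patient {df['patient_id'].iloc[i]})"
        )
    df["timestamp"] = pd.to_datetime(df["timestamp"])
    out: Dict[str, Dict[str, SampleSeries]] = {}
    for (pid, ch), g in df.groupby(["patient_id", "channel"], sort=True):
        g = g.sort_values("timestamp")
        out.setdefault(pid, {})[ch] = SampleSeries(
            ch,
            g["timestamp"].to_numpy().astype("datetime64[s]"),
            g["value"].to_numpy(dtype=float),
        )
    return out


def read_events(path) -> Dict[str, dict]:
    """Read an events CSV into per-patient monitoring metadata."""
    df = pd.read_csv(path, dtype={"patient_id": str})
    required = {"patient_id", "monitoring_start", "monitoring_end", "first_sae_time"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"events file lacks columns: {sorted(missing)}")
    out = {}
    for _, row in df.iterrows():
        sae = row["first_sae_time"]
        sae_t = None if pd.isna(sae) or str(sae).strip() == "" else np.datetime64(
            pd.to_datetime(sae)).astype("datetime64[s]")
        out[row["patient_id"]] = {
            "monitoring_start": np.datetime64(
                pd.to_datetime(row["monitoring_start"])).astype("datetime64[s]"),
            "monitoring_end": np.datetime64(
                pd.to_datetime(row["monitoring_end"])).astype("datetime64[s]"),
            "first_sae_time": sae_t,
        }
    return out


def write_streams(records, path) -> None:
    frames = []
    for rec in records:
        for ch, s in sorted(rec.series.items()):
            m = s.retained
            frames.append(pd.DataFrame({
                "patient_id": rec.patient_id,
                "timestamp": np.datetime_as_string(s.times[m]),
                "channel": ch,
                "value": np.round(s.values[m], 3),
            }))
    df = pd.concat(frames, ignore_index=True) if frames else pd.DataFrame(
        columns=["patient_id", "timestamp", "channel", "value"])
    df.to_csv(path, index=False)


def write_events(records, path) -> None:
    rows = []
    for rec in records:
        rows.append({
            "patient_id": rec.patient_id,
            "monitoring_start": np.datetime_as_string(rec.monitoring_start),
            "monitoring_end": np.datetime_as_string(rec.monitoring_end),
            "first_sae_time": (
                "" if rec.first_sae_time is None
                else np.datetime_as_string(rec.first_sae_time)),
        })
    pd.DataFrame(rows, columns=["patient_id", "monitoring_start",
                                "monitoring_end", "first_sae_time"]
                 ).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# optional ECG ingestion
# ---------------------------------------------------------------------------

_ECG_NAME = re.compile(r"^(?P<pid>.+)_(?P<minute>\d+)\.txt$")


def hr_series_from_ecg_dir(
    ecg_dir, patient_id: str, monitoring_start, config: AnalysisConfig
) -> SampleSeries:
    """Derive a per-minute HR series from per-minute ECG waveform files.

    Rejected segments (low template correlation or too few beats) simply
    contribute no sample for that minute.
    """
    monitoring_start = np.datetime64(monitoring_start, "s")
    times, values = [], []
    for f in sorted(Path(ecg_dir).iterdir()):
        m = _ECG_NAME.match(f.name)
        if not m or m.group("pid") != patient_id:
            continue
        minute = int(m.group("minute"))
        samples = np.loadtxt(f, dtype=float)
        seg = EcgSegment(minute_index=minute, samples=samples)
        res = assess_ecg_segment(seg, config.qrs_correlation_threshold)
        if res.accepted:
            times.append(monitoring_start + np.timedelta64(60 * minute, "s"))
            values.append(res.hr)
    return SampleSeries("HR", np.asarray(times, dtype="datetime64[s]"),
                        np.asarray(values, dtype=float))
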