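"""CSV/JSON readers and writers for the pipeline's file formats.

Waveforms are plain CSVs with columns ``time_s,pressure_mmhg`` at uniform
1/fs spacing; cohort manifests pair participant sessions with waveform
files and carry antihypertensive status; beat annotations and QC sidecars
mirror the delineator's output.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .beats import BeatSeries, BPWaveform, DetectionParams

__all__ = [
    "read_waveform_csv",
    "write_waveform_csv",
    "read_manifest",
    "write_beat_annotations",
    "write_qc_sidecar",
]


def write_waveform_csv(waveform: BPWaveform, path: str | Path) -> None:
    df = pd.DataFrame({
        "time_s": waveform.times(),
        "pressure_mmhg": waveform.samples,
    })
    df.to_csv(path, index=False, float_format="%.6f")


def read_waveform_csv(path: str | Path) -> BPWaveform:
    df = pd.read_csv(path)
    t = df["time_s"].to_numpy(dtype=float)
    dt = np.diff(t)
    if len(dt) == 0 or np.ptp(dt) > 1e-6:
        raise ValueError(f"{path}: time column is not uniformly spaced")
    fs = 1.0 / float(np.mean(dt))
    return BPWaveform(df["pressure_mmhg"].to_numpy(dtype=float),
                      fs=round(fs, 6), t0=float(t[0]))


def read_manifest(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    required = {"participant_id", "session", "waveform_path", "antihypertensive"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: manifest missing columns {sorted(missing)}")
    return df


def write_beat_annotations(beats: BeatSeries, path: str | Path) -> None:
    n = beats.n_beats
    trough_times = np.full(n, np.nan)
    dbp = np.full(n, np.nan)
    # troughs follow peaks pairwise within segments; align trough j to the
    # earlier peak of its pair
    j = 0
    ids = np.asarray(beats.segment_ids)
    for i in range(n - 1):
        if ids[i] == ids[i + 1]:
            trough_times[i] = beats.trough_times[j]
            dbp[i] = beats.dbp_values[j]
            j += 1
    pd.DataFrame({
        "beat_index": np.arange(n),
        "peak_time_s": beats.peak_times,
        "sbp_mmhg": beats.sbp_values,
        "trough_time_s": trough_times,
        "dbp_mmhg": dbp,
    }).to_csv(path, index=False, float_format="%.6f")


def write_qc_sidecar(beats: BeatSeries, params: DetectionParams,
                     path: str | Path) -> None:
    payload = {
        "excluded_fraction": beats.excluded_fraction,
        "accepted": beats.accepted,
        "n_beats": beats.n_beats,
        "params": {
            "min_height": params.min_height,
            "refractory_ms": params.refractory_ms,
            "artifact_bounds": list(params.artifact_bounds),
            "max_abs_slope": params.max_abs_slope,
            "max_excluded_fraction": params.max_excluded_fraction,
        },
    }
    Path(path).write_text(json.dumps(payload, indent=2))
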