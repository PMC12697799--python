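"""File I/O: spike tables (CSV/JSON), named-array containers (NPZ), and
JSON reports."""

from __future__ import annotations

import json
import warnings
from pathlib import Path

import numpy as np
import pandas as pd

from .codes import WindowSet
from .neurons import SpikeTrain
from .stimulus import FrequencyAxis, Spectrogram, SweepPair, ToneSchedule

__all__ = ["read_spike_trains", "write_spike_trains", "save_spectrogram",
           "load_spectrogram", "save_sweeps", "load_sweeps", "save_windows",
           "load_windows", "write_tone_schedule", "read_tone_schedule",
           "write_report"]


def read_spike_trains(path, duration: float | None = None) -> list:
    """Read spike trains from a CSV or JSON table with columns
    (unit_id, time_s); one SpikeTrain per unit.

    Duration is taken from the argument or inferred as the latest spike
    time. Rows unsorted within a unit are sorted with a warning; negative
    times are an error naming the offending line.
    """
    path = Path(path)
    if path.suffix.lower() == ".json":
        df = pd.DataFrame(json.loads(path.read_text()))
        if df.empty:
            df = pd.DataFrame(columns=["unit_id", "time_s"])
    else:
        df = pd.read_csv(path)
    missing = {"unit_id", "time_s"} - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    bad = df.index[df["time_s"] < 0]
    if len(bad):
        raise ValueError(f"{path}: negative spike time at line {bad[0] + 2}")
    if df.empty:
        warnings.warn(f"{path}: no spikes", stacklevel=2)
        return []
    if duration is None:
        duration = float(df["time_s"].max())
    trains = []
    for unit_id, grp in df.groupby("unit_id", sort=True):
        times = grp["time_s"].to_numpy(dtype=float)
        if np.any(np.diff(times) < 0):
            warnings.warn(f"{path}: unit {unit_id} spike times unsorted; "
                          "sorting", stacklevel=2)
            times = np.sort(times)
        trains.append(SpikeTrain(times=times, duration=duration,
                                 unit_id=str(unit_id)))
    return trains


def write_spike_trains(trains: list, path) -> None:
    rows = [(t.unit_id, s) for t in trains for s in t.times]
    pd.DataFrame(rows, columns=["unit_id", "time_s"]).to_csv(path, index=False)


def save_spectrogram(spectrogram: Spectrogram, path) -> None:
    np.savez(path, energy=spectrogram.energy, dt=spectrogram.dt,
             freq_centers_hz=spectrogram.axis.centers)


def load_spectrogram(path) -> Spectrogram:
    with np.load(path) as z:
        return Spectrogram(energy=z["energy"], dt=float(z["dt"]),
                           axis=FrequencyAxis(z["freq_centers_hz"]))


def save_sweeps(sweeps: SweepPair, path) -> None:
    np.savez(path, log2f=sweeps.log2f, trajectory_dt=sweeps.trajectory_dt,
             bounds=np.asarray(sweeps.bounds), seed=sweeps.seed)


def load_sweeps(path) -> SweepPair:
    with np.load(path) as z:
        return SweepPair(log2f=z["log2f"],
                         trajectory_dt=float(z["trajectory_dt"]),
                         bounds=tuple(z["bounds"]), seed=int(z["seed"]))


def save_windows(windows: WindowSet, path) -> None:
    np.savez(path, starts=windows.starts, vectors=windows.vectors,
             spike_counts=windows.spike_counts,
             code_kind=windows.code_kind, length=windows.length,
             stride=windows.stride, unit_ids=np.asarray(windows.unit_ids),
             duration=windows.duration, bin_dt=windows.bin_dt,
             hann_len=windows.hann_len)


def load_windows(path) -> WindowSet:
    with np.load(path) as z:
        return WindowSet(starts=z["starts"], length=float(z["length"]),
                         stride=float(z["stride"]),
                         code_kind=str(z["code_kind"]),
                         vectors=z["vectors"], spike_counts=z["spike_counts"],
                         unit_ids=tuple(str(u) for u in z["unit_ids"]),
                         duration=float(z["duration"]),
                         bin_dt=float(z["bin_dt"]),
                         hann_len=float(z["hann_len"]))


def write_tone_schedule(schedule: ToneSchedule, path) -> None:
    pd.DataFrame({"onset_s": schedule.onsets_s, "freq_hz": schedule.freqs_hz,
                  "rep": schedule.rep_index}).to_csv(path, index=False)


def read_tone_schedule(path, rate: float, n_reps: int,
                       seed: int = -1) -> ToneSchedule:
    df = pd.read_csv(path)
    return ToneSchedule(onsets_s=df["onset_s"].to_numpy(float),
                        freqs_hz=df["freq_hz"].to_numpy(float),
                        rep_index=df["rep"].to_numpy(int),
                        presentation_rate=rate, n_reps=n_reps, seed=seed)


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return _jsonable(obj.tolist())
    if isinstance(obj, (np.floating, float)):
        f = float(obj)
        if f == float("-inf"):
            return "-inf"          # no-information sentinel
        return None if f != f else f
    if isinstance(obj, np.integer):
        return int(obj)
    return obj


def write_report(report: dict, path) -> None:
    """Serialize a scalar report to JSON with stable key order."""
    Path(path).write_text(json.dumps(_jsonable(report), indent=2,
                                     sort_keys=True) + "\n")
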