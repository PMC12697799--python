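"""Per-window spike codes: the temporal code and the rate code.

The temporal code represents each analysis window (100 ms by default) by the
segment of the spike train binned at 0.5 ms and convolved with a 9 ms Hann
taper; windows are compared by Euclidean distance on these traces. The rate
code represents a window by its spike count. Group codes concatenate the
per-unit vectors. Masks select windows by spiking state (silence / spiking /
one-fires-one-silent combinatorial).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view
from scipy.signal.windows import hann

from .neurons import SpikeTrain

__all__ = ["SmoothedTrain", "WindowSet", "WindowMask", "hann_taper",
           "bin_and_smooth", "make_windows", "code_distance", "make_mask",
           "mean_evoked_rate"]

CODE_KINDS = ("temporal", "rate")
MASK_KINDS = ("silence", "spiking", "combinatorial")


@dataclass(frozen=True)
class SmoothedTrain:
    """Spike counts at ``bin_dt`` convolved with a peak-normalized Hann taper."""

    values: np.ndarray
    bin_dt: float
    duration: float


@dataclass(frozen=True)
class WindowSet:
    """Per-window code vectors for a group of units.

    ``vectors`` is [n_windows x dim]: for the temporal code the concatenated
    smoothed-trace segments of all units, for the rate code the concatenated
    per-unit spike counts. ``spike_counts`` ([n_windows x n_units]) is kept
    for both codes because the silence/spiking masks are defined on counts.
    """

    starts: np.ndarray
    length: float
    stride: float
    code_kind: str
    vectors: np.ndarray
    spike_counts: np.ndarray
    unit_ids: tuple
    duration: float
    bin_dt: float = 5e-4
    hann_len: float = 9e-3

    @property
    def n_windows(self) -> int:
        return self.starts.size

    @property
    def n_units(self) -> int:
        return len(self.unit_ids)


@dataclass(frozen=True)
class WindowMask:
    """Boolean window selection with the defining unit roles."""

    kind: str
    flags: np.ndarray
    params: dict = field(default_factory=dict)

    @property
    def n_selected(self) -> int:
        return int(self.flags.sum())


def hann_taper(bin_dt: float = 5e-4, hann_len: float = 9e-3) -> np.ndarray:
    """Peak-normalized symmetric Hann taper of total support ``hann_len``.

    9 ms at 0.5 ms bins discretizes to 19 taps (center bin + 9 each side);
    the discretized tap count must be odd so the taper has a center bin.
    """
    if bin_dt <= 0:
        raise ValueError("bin_dt must be positive")
    n_taps = int(round(hann_len / bin_dt)) + 1
    if n_taps < 1 or n_taps % 2 == 0:
        raise ValueError("hann_len must discretize to an odd tap count "
                         f"(got {n_taps} taps)")
    if n_taps == 1:
        return np.ones(1)
    h = hann(n_taps, sym=True)
    return h / h.max()


def bin_and_smooth(train: SpikeTrain, bin_dt: float = 5e-4,
                   hann_len: float = 9e-3) -> SmoothedTrain:
    """Bin a spike train and convolve with the Hann taper (same-length output)."""
    taper = hann_taper(bin_dt, hann_len)
    n_bins = int(round(train.duration / bin_dt))
    counts = np.zeros(n_bins)
    if train.n_spikes:
        idx = np.minimum((train.times / bin_dt).astype(int), n_bins - 1)
        np.add.at(counts, idx, 1.0)
    values = np.convolve(counts, taper, mode="same")
    return SmoothedTrain(values=values, bin_dt=bin_dt, duration=train.duration)


def make_windows(units: list, code_kind: str, length: float = 0.100,
                 stride: float = 0.010, bin_dt: float = 5e-4,
                 hann_len: float = 9e-3) -> WindowSet:
    """Slice a group of spike trains into per-window code vectors.

    Windows start at {0, stride, 2*stride, ...} while start+length fits
    inside the recording. Temporal vectors concatenate the smoothed-trace
    segments of all units; rate vectors concatenate the per-unit counts.
    """
    if not units:
        raise ValueError("empty unit list")
    if code_kind not in CODE_KINDS:
        raise ValueError(f"code_kind must be one of {CODE_KINDS}")
    if stride <= 0:
        raise ValueError("stride must be positive")
    duration = units[0].duration
    if any(u.duration != duration for u in units):
        raise ValueError("all units must share the same duration")
    if length > duration:
        raise ValueError("window length exceeds the recording duration")
    n_win = int(np.floor((duration - length) / stride + 1e-9)) + 1
    starts = np.arange(n_win) * stride

    counts = np.empty((n_win, len(units)), dtype=np.int64)
    for j, u in enumerate(units):
        counts[:, j] = (np.searchsorted(u.times, starts + length, "left")
                        - np.searchsorted(u.times, starts, "left"))

    if code_kind == "rate":
        vectors = counts.astype(np.float32)
    else:
        sratio = stride / bin_dt
        if abs(sratio - round(sratio)) > 1e-9:
            raise ValueError("stride must be an integer multiple of bin_dt")
        l_bins = int(round(length / bin_dt))
        start_bins = np.round(starts / bin_dt).astype(int)
        per_unit = []
        for u in units:
            trace = bin_and_smooth(u, bin_dt, hann_len).values.astype(np.float32)
            segs = sliding_window_view(trace, l_bins)[start_bins]
            per_unit.append(segs)
        vectors = per_unit[0] if len(per_unit) == 1 else \
            np.concatenate(per_unit, axis=1)
    return WindowSet(starts=starts, length=length, stride=stride,
                     code_kind=code_kind, vectors=np.ascontiguousarray(vectors),
                     spike_counts=counts,
                     unit_ids=tuple(u.unit_id for u in units),
                     duration=duration, bin_dt=bin_dt, hann_len=hann_len)


def code_distance(v1: np.ndarray, v2: np.ndarray) -> float:
    """Euclidean distance between two code vectors of equal dimensionality."""
    v1 = np.atleast_1d(np.asarray(v1, dtype=float))
    v2 = np.atleast_1d(np.asarray(v2, dtype=float))
    if v1.shape != v2.shape:
        raise ValueError(f"dimensionality mismatch: {v1.shape} vs {v2.shape}")
    return float(np.linalg.norm(v1 - v2))


def make_mask(windows: WindowSet, kind: str,
              roles: dict | None = None) -> WindowMask:
    """Build a window mask from per-window spike counts.

    silence: zero spikes in *all* units of the group; spiking: >= 1 spike in
    any unit; combinatorial (exactly two units): the 'spiker' unit fires and
    the 'silent' unit does not, with ``roles={'spiker': id, 'silent': id}``.
    """
    if kind not in MASK_KINDS:
        raise ValueError(f"mask kind must be one of {MASK_KINDS}")
    counts = windows.spike_counts
    if kind == "silence":
        return WindowMask("silence", counts.sum(axis=1) == 0)
    if kind == "spiking":
        return WindowMask("spiking", counts.sum(axis=1) > 0)
    if windows.n_units != 2:
        raise ValueError("combinatorial mask requires exactly two units")
    roles = roles or {"spiker": windows.unit_ids[0],
                      "silent": windows.unit_ids[1]}
    try:
        i_spk = windows.unit_ids.index(roles["spiker"])
        i_sil = windows.unit_ids.index(roles["silent"])
    except (KeyError, ValueError) as exc:
        raise ValueError(f"roles must name the two units {windows.unit_ids}") \
            from exc
    flags = (counts[:, i_spk] > 0) & (counts[:, i_sil] == 0)
    return WindowMask("combinatorial", flags, params=dict(roles))


def mean_evoked_rate(train: SpikeTrain) -> float:
    """Mean firing rate in sp/s: spike count / duration."""
    if train.duration <= 0:
        raise ValueError("duration must be positive")
    return train.n_spikes / train.duration
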