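"""Synthetic spike trains with known ground truth.

Two kinds of model units:

* homogeneous Poisson processes, the null against which decoding
  significance is calibrated, and
* linear-nonlinear-Poisson (LNP) encoders with a separable Gaussian
  spectrotemporal filter whose best frequency, bandwidth, latency, gain and
  timing jitter are all controllable ground truth.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np

from .stimulus import Spectrogram

__all__ = ["SpikeTrain", "EncoderSpec", "simulate_poisson", "simulate_lnp",
           "lnp_rate", "merge_units", "precise_encoder",
           "jittered_slow_encoder"]


@dataclass(frozen=True)
class SpikeTrain:
    """Sorted spike times of one unit over [0, duration]."""

    times: np.ndarray
    duration: float
    unit_id: str = "unit"

    def __post_init__(self):
        t = np.asarray(self.times, dtype=float)
        if t.size and (np.any(~np.isfinite(t)) or t.min() < 0
                       or t.max() > self.duration):
            raise ValueError("spike times must be finite and within "
                             "[0, duration]")
        if np.any(np.diff(t) < 0):
            raise ValueError("spike times must be non-decreasing")
        object.__setattr__(self, "times", t)

    @property
    def n_spikes(self) -> int:
        return self.times.size


@dataclass(frozen=True)
class EncoderSpec:
    """Parameters of a model unit.

    kind='poisson' uses only ``baseline_rate``; kind='lnp' adds a separable
    Gaussian spectrotemporal filter (SD ``bandwidth`` octaves in
    log-frequency x SD ``kernel_width`` s in time), a response ``latency``,
    a ``gain`` (sp/s per unit filtered spectrogram energy), Gaussian
    spike-time ``jitter`` and an absolute ``refractory`` period.
    """

    kind: str = "lnp"
    baseline_rate: float = 2.0    # sp/s
    gain: float = 60.0            # sp/s per unit drive
    bf: float = 16_000.0          # Hz
    bandwidth: float = 0.5        # octaves (SD of log-frequency tuning)
    latency: float = 0.015        # s
    kernel_width: float = 0.005   # s (temporal integration SD)
    jitter: float = 0.0           # s (spike-time jitter SD)
    refractory: float = 0.001     # s
    seed: int = 0

    def __post_init__(self):
        if self.kind not in ("poisson", "lnp"):
            raise ValueError("kind must be 'poisson' or 'lnp'")
        if self.baseline_rate < 0 or self.gain < 0:
            raise ValueError("rates and gain must be nonnegative")
        if self.latency < 0:
            raise ValueError("latency must be nonnegative")

    def with_seed(self, seed: int) -> "EncoderSpec":
        return replace(self, seed=seed)


def simulate_poisson(rate: float, duration: float, seed: int = 0,
                     unit_id: str = "poisson") -> SpikeTrain:
    """Homogeneous Poisson spike train at ``rate`` sp/s."""
    if rate < 0:
        raise ValueError("rate must be nonnegative")
    if duration <= 0:
        raise ValueError("duration must be positive")
    rng = np.random.default_rng(seed)
    n = rng.poisson(rate * duration)
    times = np.sort(rng.uniform(0.0, duration, size=n))
    return SpikeTrain(times=times, duration=duration, unit_id=unit_id)


def lnp_rate(spec: EncoderSpec, stimulus: Spectrogram) -> np.ndarray:
    """Instantaneous firing rate (sp/s) of an LNP unit on the stimulus grid.

    rate(t) = baseline + gain * rectify(G (*) S)(t - latency), where G is a
    separable Gaussian kernel: unit-sum weights over log-frequency (SD =
    ``bandwidth`` octaves, centered on ``bf``) and a unit-area Gaussian in
    time (SD = ``kernel_width``). Rectification is half-wave.
    """
    axis = stimulus.axis
    if not (axis.centers[0] <= spec.bf <= axis.centers[-1]):
        raise ValueError(f"bf {spec.bf} Hz outside the stimulus band "
                         f"[{axis.centers[0]}, {axis.centers[-1]}] Hz")
    w = np.exp(-0.5 * ((axis.log2_centers - np.log2(spec.bf))
                       / max(spec.bandwidth, 1e-9)) ** 2)
    w /= w.sum()
    drive = w @ stimulus.energy  # weighted energy per time bin
    if spec.kernel_width > 0:
        half = max(1, int(np.ceil(4 * spec.kernel_width / stimulus.dt)))
        tk = np.arange(-half, half + 1) * stimulus.dt
        g = np.exp(-0.5 * (tk / spec.kernel_width) ** 2)
        g /= g.sum()
        drive = np.convolve(drive, g, mode="same")
    shift = int(round(spec.latency / stimulus.dt))
    if shift:
        drive = np.concatenate([np.zeros(shift), drive[:-shift or None]])
    return spec.baseline_rate + spec.gain * np.maximum(drive, 0.0)


def simulate_lnp(spec: EncoderSpec, stimulus: Spectrogram,
                 sample_dt: float = 5e-4,
                 unit_id: str | None = None) -> SpikeTrain:
    """Spike train of an LNP encoder driven by a stimulus spectrogram.

    Spikes are drawn as an inhomogeneous Poisson process (per-bin Bernoulli
    at ``sample_dt``), each jittered by Gaussian(0, jitter) and pruned to the
    absolute refractory period.
    """
    if spec.kind != "lnp":
        raise ValueError("simulate_lnp requires an 'lnp' EncoderSpec")
    rate = lnp_rate(spec, stimulus)
    ratio = int(round(stimulus.dt / sample_dt))
    if abs(stimulus.dt / sample_dt - ratio) > 1e-9 or ratio < 1:
        raise ValueError("stimulus dt must be an integer multiple of sample_dt")
    fine = np.repeat(rate, ratio)
    p = fine * sample_dt
    if p.max(initial=0.0) > 0.1:
        warnings.warn("rate*dt exceeds 0.1; Bernoulli approximation of the "
                      "Poisson process is getting coarse", stacklevel=2)
    rng = np.random.default_rng(spec.seed)
    hits = np.flatnonzero(rng.random(p.size) < p)
    times = (hits + 0.5) * sample_dt
    if spec.jitter > 0 and times.size:
        times = times + rng.normal(0.0, spec.jitter, size=times.size)
        times = np.sort(np.clip(times, 0.0, stimulus.duration))
    times = _prune_refractory(times, spec.refractory)
    return SpikeTrain(times=times, duration=stimulus.duration,
                      unit_id=unit_id or f"lnp_bf{spec.bf:.0f}")


def _prune_refractory(times: np.ndarray, refractory: float) -> np.ndarray:
    """Delete any spike closer than ``refractory`` to its kept predecessor."""
    if refractory <= 0 or times.size < 2:
        return times
    kept = [times[0]]
    for t in times[1:]:
        if t - kept[-1] >= refractory:
            kept.append(t)
    return np.asarray(kept)


def precise_encoder(bf: float = 16_000.0, latency: float = 0.010,
                    seed: int = 0) -> EncoderSpec:
    """Auditory-nerve-like precise burst encoder.

    Sharp tuning (0.125 oct), ~1 ms temporal integration, no jitter and a
    high gain: spikes come in brief high-rate bursts locked to the moments a
    sweep voice crosses the unit's best frequency, so within-window spike
    *timing* carries most of the information. Mean rate on the default
    stimulus is ~30-50 sp/s.
    """
    return EncoderSpec(kind="lnp", baseline_rate=0.2, gain=500.0, bf=bf,
                       bandwidth=0.125, latency=latency, kernel_width=0.001,
                       jitter=0.0, refractory=0.001, seed=seed)


def jittered_slow_encoder(bf: float = 16_000.0, latency: float = 0.010,
                          seed: int = 0) -> EncoderSpec:
    """Cortex-like slow rate-modulated encoder.

    Same tuning and gain as :func:`precise_encoder` but with 50 ms temporal
    integration and 20 ms Gaussian spike-time jitter: fine timing is
    destroyed while the window spike count still tracks the stimulus.
    """
    return EncoderSpec(kind="lnp", baseline_rate=0.2, gain=500.0, bf=bf,
                       bandwidth=0.125, latency=latency, kernel_width=0.050,
                       jitter=0.020, refractory=0.001, seed=seed)


def merge_units(trains: list) -> SpikeTrain:
    """Merge single units into a multiunit: the sorted union of spike times."""
    if not trains:
        raise ValueError("need at least one train")
    durations = {t.duration for t in trains}
    if len(durations) > 1:
        raise ValueError(f"mixed durations: {sorted(durations)}")
    times = np.sort(np.concatenate([t.times for t in trains]))
    unit_id = "+".join(t.unit_id for t in trains)
    return SpikeTrain(times=times, duration=trains[0].duration,
                      unit_id=unit_id)
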