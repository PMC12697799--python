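"""Random double sweep (RDS) stimuli, tone schedules and complexity traces.

The RDS is a continuous complex sound made of two pure-tone "voices" whose
instantaneous frequencies wander randomly (frequency modulation restricted to
below a cutoff, 10 Hz by default) across a wide band (2-90 kHz by default).
Because the stream never repeats, any segment can only be reconstructed from
neural responses to *variations* of that segment, which is what makes it a
good probe of neural code reliability.

Stimuli are represented as spectrograms: an energy grid over a log-spaced
frequency axis, one Gaussian ridge per voice.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import uniform_filter1d


__all__ = [
    "FrequencyAxis",
    "SweepPair",
    "Spectrogram",
    "ToneSchedule",
    "ComplexityTrace",
    "generate_rds",
    "render_spectrogram",
    "render_tone_spectrogram",
    "generate_tone_schedule",
    "compute_complexity",
    "correlate_reliability_with_complexity",
]

#: octave distance below which the proximity trace is floored before log2
PROXIMITY_FLOOR_OCTAVES = 1e-3


@dataclass(frozen=True)
class FrequencyAxis:
    """Log2-uniformly spaced channel center frequencies in Hz."""

    centers: np.ndarray

    def __post_init__(self):
        c = np.asarray(self.centers, dtype=float)
        if c.ndim != 1 or c.size < 2:
            raise ValueError("FrequencyAxis needs at least two channel centers")
        if np.any(np.diff(c) <= 0):
            raise ValueError("channel centers must be strictly increasing")
        steps = np.diff(np.log2(c))
        if not np.allclose(steps, steps[0], rtol=1e-6, atol=1e-9):
            raise ValueError("channel centers must be log2-uniformly spaced")
        object.__setattr__(self, "centers", c)

    @classmethod
    def default(cls, n_channels: int = 45, fmin: float = 2_000.0,
                fmax: float = 90_000.0) -> "FrequencyAxis":
        """45 channels covering 5.5 octaves (2-90 kHz) by default."""
        span = np.log2(fmax / fmin)
        return cls(fmin * 2.0 ** np.linspace(0.0, span, n_channels))

    @property
    def n_channels(self) -> int:
        return self.centers.size

    @property
    def span_octaves(self) -> float:
        return float(np.log2(self.centers[-1] / self.centers[0]))

    @property
    def spacing_octaves(self) -> float:
        return self.span_octaves / (self.n_channels - 1)

    @property
    def log2_centers(self) -> np.ndarray:
        return np.log2(self.centers)


@dataclass(frozen=True)
class SweepPair:
    """Two instantaneous-frequency trajectories in log2(Hz)."""

    log2f: np.ndarray          # shape (2, n_samples)
    trajectory_dt: float       # s
    bounds: tuple              # (fmin, fmax) Hz
    seed: int

    def __post_init__(self):
        x = np.asarray(self.log2f, dtype=float)
        if x.ndim != 2 or x.shape[0] != 2:
            raise ValueError("log2f must have shape (2, n_samples)")
        if not np.all(np.isfinite(x)):
            raise ValueError("trajectories must be finite")
        lo, hi = np.log2(self.bounds[0]), np.log2(self.bounds[1])
        if x.min() < lo - 1e-9 or x.max() > hi + 1e-9:
            raise ValueError("trajectory samples outside the stated bounds")
        object.__setattr__(self, "log2f", x)

    @property
    def duration(self) -> float:
        return self.log2f.shape[1] * self.trajectory_dt

    @property
    def n_samples(self) -> int:
        return self.log2f.shape[1]


@dataclass(frozen=True)
class Spectrogram:
    """Stimulus energy grid, [n_channels x n_time], arbitrary nonneg units."""

    energy: np.ndarray
    dt: float
    axis: FrequencyAxis

    def __post_init__(self):
        e = np.asarray(self.energy, dtype=float)
        if e.ndim != 2 or e.shape[0] != self.axis.n_channels:
            raise ValueError("energy must be [n_channels x n_time]")
        if e.size and e.min() < 0:
            raise ValueError("spectrogram energy must be nonnegative")
        object.__setattr__(self, "energy", e)

    @property
    def n_time(self) -> int:
        return self.energy.shape[1]

    @property
    def duration(self) -> float:
        return self.n_time * self.dt

    @property
    def times(self) -> np.ndarray:
        """Bin start times in s."""
        return np.arange(self.n_time) * self.dt


@dataclass(frozen=True)
class ToneSchedule:
    """Randomized pure-tone presentation order for receptive-field mapping."""

    onsets_s: np.ndarray
    freqs_hz: np.ndarray
    rep_index: np.ndarray
    presentation_rate: float
    n_reps: int
    seed: int

    @property
    def n_events(self) -> int:
        return self.onsets_s.size

    @property
    def frequencies(self) -> np.ndarray:
        return np.unique(self.freqs_hz)

    @property
    def duration(self) -> float:
        return self.n_events / self.presentation_rate


@dataclass(frozen=True)
class ComplexityTrace:
    """Per-time-bin stimulus complexity feature; NaN marks undefined bins."""

    kind: str
    values: np.ndarray
    dt: float
    params: dict = field(default_factory=dict)


def generate_rds(duration: float = 300.0, trajectory_dt: float = 5e-4,
                 fmin: float = 2_000.0, fmax: float = 90_000.0,
                 speed_cutoff: float = 10.0, seed: int = 0,
                 rms_speed: float = 16.0) -> SweepPair:
    """Generate the random double sweep: two independent random FM voices.

    Each voice's sweep *velocity* (d log2 f / dt) is seeded Gaussian white
    noise brick-wall low-pass filtered at ``speed_cutoff`` in the Fourier
    domain (zero phase), scaled to ``rms_speed``; the log2-frequency
    trajectory integrates this velocity from a random starting frequency and
    is reflected into [fmin, fmax] at the band edges. The stationary
    occupancy of such a reflected walk is uniform across the band — every
    channel of the analysis filterbank is probed equally, as a
    receptive-field mapping stimulus requires — and the only FM power above
    the cutoff is the negligible contribution of the reflection kinks.

    Parameters
    ----------
    duration : total stimulus duration in s (paper protocol: 5 min).
    trajectory_dt : trajectory sampling step in s.
    fmin, fmax : band edges in Hz.
    speed_cutoff : maximum FM modulation frequency in Hz.
    seed : RNG seed; the same seed yields bit-identical trajectories.
    rms_speed : RMS sweep speed in octaves/s. The default traverses the
        5.5-octave band roughly once per second, so band occupancy mixes
        within seconds — far shorter than the stimulus — and no static
        spectral profile builds up.
    """
    if duration <= 0:
        raise ValueError("duration must be positive")
    if not fmin < fmax:
        raise ValueError("need fmin < fmax")
    if speed_cutoff <= 0:
        raise ValueError("speed_cutoff must be positive")
    if rms_speed <= 0:
        raise ValueError("rms_speed must be positive")
    n = int(round(duration / trajectory_dt))
    if n < 4:
        raise ValueError("duration too short for the trajectory step")
    rng = np.random.default_rng(seed)
    lo, hi = np.log2(fmin), np.log2(fmax)

    freqs = np.fft.rfftfreq(n, trajectory_dt)
    keep = freqs <= speed_cutoff
    trajs = np.empty((2, n))
    for v in range(2):
        white = rng.standard_normal(n)
        spec = np.fft.rfft(white)
        spec[~keep] = 0.0
        vel = np.fft.irfft(spec, n)
        sd = vel.std()
        start = rng.uniform(lo, hi)
        if sd == 0:  # degenerate, keep the voice parked where it started
            trajs[v] = start
            continue
        vel *= rms_speed / sd
        trajs[v] = _reflect_into(start + np.cumsum(vel) * trajectory_dt,
                                 lo, hi)
    return SweepPair(log2f=trajs, trajectory_dt=trajectory_dt,
                     bounds=(fmin, fmax), seed=seed)


def _reflect_into(x: np.ndarray, lo: float, hi: float) -> np.ndarray:
    """Fold values into [lo, hi] by reflection at the edges."""
    span = hi - lo
    y = np.mod(x - lo, 2 * span)
    y = np.where(y > span, 2 * span - y, y)
    return y + lo


def render_spectrogram(sweeps: SweepPair, axis: FrequencyAxis | None = None,
                       dt: float = 5e-3,
                       ridge_width: float = 0.125) -> Spectrogram:
    """Render a sweep pair as a spectrogram with one Gaussian ridge per voice.

    Each time column holds, per voice, a unit-peak Gaussian bump in
    log-frequency centered on the voice's instantaneous frequency with SD
    ``ridge_width`` octaves. Ridge tails are reflected at the band edges
    (matching the reflective voice trajectories) so that edge channels
    capture the full ridge energy and the time-averaged spectral profile is
    flat; without this, a static edge deficit shared by the stimulus and any
    average of its segments biases correlation-based scores. Coincident
    voices are combined by maximum so the energy never doubles.
    """
    if axis is None:
        axis = FrequencyAxis.default()
    if ridge_width <= 0:
        raise ValueError("ridge_width must be positive")
    ratio = dt / sweeps.trajectory_dt
    if abs(ratio - round(ratio)) > 1e-9 or round(ratio) < 1:
        raise ValueError("dt must be an integer multiple of trajectory_dt")
    ratio = int(round(ratio))
    n_time = sweeps.n_samples // ratio
    # block-average the trajectory onto the spectrogram grid
    tr = sweeps.log2f[:, : n_time * ratio].reshape(2, n_time, ratio).mean(axis=2)
    lo, hi = np.log2(sweeps.bounds[0]), np.log2(sweeps.bounds[1])
    lc = axis.log2_centers[:, None]
    energy = np.zeros((axis.n_channels, n_time))
    for v in range(2):
        f = tr[v][None, :]
        bump = np.exp(-0.5 * ((lc - f) / ridge_width) ** 2)
        # reflected tails at both band edges
        bump += np.exp(-0.5 * ((lc - (2 * lo - f)) / ridge_width) ** 2)
        bump += np.exp(-0.5 * ((lc - (2 * hi - f)) / ridge_width) ** 2)
        np.maximum(energy, bump, out=energy)
    return Spectrogram(energy=energy, dt=dt, axis=axis)


def generate_tone_schedule(axis: FrequencyAxis | None = None,
                           rate: float = 4.15, n_reps: int = 8,
                           seed: int = 0) -> ToneSchedule:
    """Random-order pure-tone schedule: each channel frequency ``n_reps``
    times at ``rate`` presentations per second (paper protocol: 45
    frequencies, 4.15 Hz, 8 repetitions, ~86.75 s)."""
    if axis is None:
        axis = FrequencyAxis.default()
    if rate <= 0:
        raise ValueError("rate must be positive")
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    rng = np.random.default_rng(seed)
    freqs = rng.permutation(np.repeat(axis.centers, n_reps))
    onsets = np.arange(freqs.size) / rate
    # repetition index = running occurrence count of each frequency
    rep = np.zeros(freqs.size, dtype=int)
    seen: dict = {}
    for i, f in enumerate(freqs):
        rep[i] = seen.get(f, 0)
        seen[f] = rep[i] + 1
    return ToneSchedule(onsets_s=onsets, freqs_hz=freqs, rep_index=rep,
                        presentation_rate=rate, n_reps=n_reps, seed=seed)


def render_tone_spectrogram(schedule: ToneSchedule,
                            axis: FrequencyAxis | None = None,
                            dt: float = 5e-3, tone_duration: float = 0.05,
                            ridge_width: float = 0.125) -> Spectrogram:
    """Render a tone schedule as rectangular-duration Gaussian ridges
    (50 ms tones by default; no gamma-tone temporal envelope)."""
    if axis is None:
        axis = FrequencyAxis.default()
    n_time = int(np.ceil(schedule.duration / dt))
    energy = np.zeros((axis.n_channels, n_time))
    lc = axis.log2_centers
    n_on = max(1, int(round(tone_duration / dt)))
    for onset, f in zip(schedule.onsets_s, schedule.freqs_hz):
        i0 = int(round(onset / dt))
        bump = np.exp(-0.5 * ((lc - np.log2(f)) / ridge_width) ** 2)
        seg = energy[:, i0: i0 + n_on]
        if seg.shape[1]:
            np.maximum(seg, bump[:, None], out=seg)
    return Spectrogram(energy=energy, dt=dt, axis=axis)


def compute_complexity(sweeps: SweepPair, kind: str,
                       window: float | None = None) -> ComplexityTrace:
    """Per-time-bin stimulus complexity features of the two voices.

    kind='proximity'
        log2 of the absolute octave distance between the voices (floored at
        ``PROXIMITY_FLOOR_OCTAVES`` before the log). Closer voices are harder
        to resolve by a single neuron.
    kind='speed'
        mean of the two absolute FM speeds |d log2 f / dt| in octaves/s.
    kind='dissimilarity'
        Pearson correlation of the two trajectories over a sliding window
        (default 100 ms) centered on each bin; strongly negative values mean
        opposite local motion. Edge and zero-variance bins are NaN.
    """
    x1, x2 = sweeps.log2f
    dt = sweeps.trajectory_dt
    if kind == "proximity":
        d = np.abs(x1 - x2)
        values = np.log2(np.maximum(d, PROXIMITY_FLOOR_OCTAVES))
        params = {"floor_octaves": PROXIMITY_FLOOR_OCTAVES}
    elif kind == "speed":
        s1 = np.abs(np.gradient(x1, dt))
        s2 = np.abs(np.gradient(x2, dt))
        values = 0.5 * (s1 + s2)
        params = {}
    elif kind == "dissimilarity":
        if window is None:
            raise ValueError("dissimilarity requires a window length")
        w = int(round(window / dt))
        if w < 2:
            raise ValueError("dissimilarity window too short")
        values = _sliding_pearson(x1, x2, w)
        params = {"window_s": window}
    else:
        raise ValueError(f"unknown complexity kind: {kind!r}")
    return ComplexityTrace(kind=kind, values=values, dt=dt, params=params)


def _sliding_pearson(x: np.ndarray, y: np.ndarray, w: int) -> np.ndarray:
    """Centered sliding-window Pearson correlation; NaN at edges and where
    either series has zero variance within the window."""
    mx = uniform_filter1d(x, w, mode="nearest")
    my = uniform_filter1d(y, w, mode="nearest")
    mxx = uniform_filter1d(x * x, w, mode="nearest")
    myy = uniform_filter1d(y * y, w, mode="nearest")
    mxy = uniform_filter1d(x * y, w, mode="nearest")
    cov = mxy - mx * my
    vx = np.maximum(mxx - mx * mx, 0.0)
    vy = np.maximum(myy - my * my, 0.0)
    denom = np.sqrt(vx * vy)
    with np.errstate(invalid="ignore", divide="ignore"):
        r = np.where(denom > 1e-15, cov / np.maximum(denom, 1e-300), np.nan)
    r = np.clip(r, -1.0, 1.0, out=r)
    half = w // 2
    r[:half] = np.nan
    if half > 0:
        r[-half:] = np.nan
    return r


def correlate_reliability_with_complexity(corr_t: np.ndarray, corr_dt: float,
                                          trace: ComplexityTrace,
                                          min_bins: int = 3):
    """Pearson r between a per-time reliability profile and a complexity trace.

    The complexity trace (at trajectory resolution) is block-averaged onto
    the decoder's evaluation-time grid (``corr_dt`` bins) before correlating.
    Returns ``(r, n_bins)``; r is NaN (undefined-correlation sentinel) when
    either series is constant over the valid bins.
    """
    corr_t = np.asarray(corr_t, dtype=float)
    ratio = corr_dt / trace.dt
    if abs(ratio - round(ratio)) > 1e-6 or round(ratio) < 1:
        raise ValueError("corr_dt must be an integer multiple of the trace dt")
    ratio = int(round(ratio))
    n = min(corr_t.size, trace.values.size // ratio)
    blocks = trace.values[: n * ratio].reshape(n, ratio)
    good = np.isfinite(blocks)
    cnt = good.sum(axis=1)
    tvals = np.where(cnt > 0,
                     np.where(good, blocks, 0.0).sum(axis=1)
                     / np.maximum(cnt, 1), np.nan)
    a, b = corr_t[:n], tvals
    valid = np.isfinite(a) & np.isfinite(b)
    n_valid = int(valid.sum())
    if n_valid < min_bins:
        raise ValueError(f"only {n_valid} overlapping valid bins (< {min_bins})")
    a, b = a[valid], b[valid]
    if np.ptp(a) == 0 or np.ptp(b) == 0:
        return float("nan"), n_valid
    r = np.corrcoef(a, b)[0, 1]
    return float(r), n_valid
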