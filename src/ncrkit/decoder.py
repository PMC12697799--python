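"""The neural code reliability (NCR) decoder.

For each evaluation window of the response, the decoder finds the k spiking
patterns most similar to it (k = 100 by default), excludes candidates that
overlap the query in time (otherwise self-matching trivially inflates the
score), and averages the stimulus segments behind those patterns at one or
more stimulus-to-response lags. The reconstruction is scored by

    NCR = log10 |Corr[S; N]|

the log absolute Pearson correlation between actual and predicted
spectrograms over all covered pixels, together with per-time (Corr(t)) and
per-frequency (Corr(f)) correlation profiles. Significance is calibrated on
homogeneous Poisson spike trains decoded against the same stimulus.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from ._kernels import accumulate_reconstruction, select_k_rows
from .codes import WindowMask, WindowSet, make_mask, make_windows
from .neurons import simulate_poisson
from .stimulus import Spectrogram

__all__ = ["NeighborTable", "DecodedStimulus", "DecodingResult",
           "NullCalibration", "find_neighbors", "reconstruct", "score",
           "decode", "scan_lags", "scan_window_sizes", "calibrate_null",
           "DEFAULT_LAGS"]

#: stimulus segment shifts averaged in the reconstruction: the segment for a
#: window starting at w is stimulus[w+lag : w+lag+length], so a negative lag
#: means the stimulus precedes the spikes it is decoded from.
DEFAULT_LAGS = (-0.010, 0.0)

#: default window-size scan grid in s
DEFAULT_WINDOW_SIZES = (0.012, 0.024, 0.048, 0.100, 0.200)

# relative/absolute tolerance (on squared distances) within which candidates
# at the k-th distance count as tied; ties are resolved by seeded sampling
_TIE_RTOL = 1e-4
_TIE_ATOL = 1e-12


class CapacityError(ValueError):
    """Raised when a query has fewer than k admissible candidates."""


@dataclass(frozen=True)
class NeighborTable:
    """k nearest non-overlapping candidate windows per query window."""

    query_indices: np.ndarray      # window indices of the queries
    neighbor_indices: np.ndarray   # [n_query x k] window indices
    distances: np.ndarray          # [n_query x k], non-decreasing per row
    query_starts: np.ndarray       # s
    neighbor_starts: np.ndarray    # [n_query x k] s
    window_length: float
    k: int
    exclusion_halfwidth: float
    tie_seed: int

    @property
    def n_queries(self) -> int:
        return self.query_indices.size


@dataclass(frozen=True)
class DecodedStimulus:
    """Reconstruction on the stimulus grid; NaN where nothing was placed."""

    predicted: np.ndarray     # [n_channels x n_time]
    coverage: np.ndarray      # per-time-bin count of window placements
    lags: tuple
    dt: float
    n_dropped_segments: int = 0


@dataclass(frozen=True)
class DecodingResult:
    """NCR score with time/frequency correlation profiles.

    ``ncr`` is log10 |corr| and is always <= 0; a constant (zero-variance)
    prediction yields the no-information sentinel ncr = -inf with
    corr_signed = NaN.
    """

    ncr: float
    corr_signed: float
    corr_t: np.ndarray
    corr_f: np.ndarray
    dt: float
    code_kind: str | None = None
    window_length: float | None = None
    stride: float | None = None
    eval_stride: float | None = None
    lags: tuple | None = None
    mask_kind: str = "full"
    k: int | None = None
    decoded: DecodedStimulus | None = None


@dataclass(frozen=True)
class NullCalibration:
    """Pooled null NCR distribution from Poisson surrogate trains."""

    samples: dict                 # code_kind -> np.ndarray of NCR values
    rates: np.ndarray             # sp/s per train
    n_trains: int
    percentile: float
    threshold: float
    seed: int
    params: dict = field(default_factory=dict)

    def pooled(self) -> np.ndarray:
        return np.concatenate([np.asarray(v) for v in self.samples.values()])

    def rate_slope(self, code_kind: str | None = None):
        """Least-squares slope of null NCR on Poisson rate (with stderr and
        p-value); the null NCR should not depend on firing rate."""
        from scipy.stats import linregress
        if code_kind is None:
            x = np.concatenate([self.rates] * len(self.samples))
            y = self.pooled()
        else:
            x, y = self.rates, np.asarray(self.samples[code_kind])
        good = np.isfinite(y)
        return linregress(x[good], y[good])


def _exclusion_bins(exclusion_halfwidth: float, stride: float) -> int:
    """Largest window-index offset m with m*stride < exclusion_halfwidth."""
    return max(0, int(math.ceil(exclusion_halfwidth / stride - 1e-9)) - 1)


def find_neighbors(windows: WindowSet, k: int = 100,
                   exclusion_halfwidth: float | None = None,
                   tie_seed: int = 0,
                   query_indices: np.ndarray | None = None,
                   candidate_indices: np.ndarray | None = None,
                   chunk: int = 1024) -> NeighborTable:
    """For each query window, the k candidates with the smallest code
    distance among windows not overlapping the query in time.

    Candidates with |start - query start| < ``exclusion_halfwidth`` (default:
    the window length) are excluded. Ties at the k-th distance are resolved
    by uniform sampling seeded per query from (tie_seed, query index), so the
    result does not depend on chunking.
    """
    n = windows.n_windows
    qidx = np.arange(n) if query_indices is None \
        else np.asarray(query_indices, dtype=int)
    cidx = np.arange(n) if candidate_indices is None \
        else np.asarray(candidate_indices, dtype=int)
    if qidx.size == 0 or cidx.size == 0:
        raise ValueError("empty query or candidate set")
    excl = windows.length if exclusion_halfwidth is None else exclusion_halfwidth
    m = _exclusion_bins(excl, windows.stride)

    # fail fast on capacity: worst query = most excluded candidates
    lo = np.searchsorted(cidx, qidx - m, side="left")
    hi = np.searchsorted(cidx, qidx + m, side="right")
    n_valid = cidx.size - (hi - lo)
    worst = int(np.argmin(n_valid))
    if n_valid[worst] < k:
        raise CapacityError(
            f"query window at t={qidx[worst] * windows.stride:.3f}s has only "
            f"{n_valid[worst]} admissible candidates (< k={k}); reduce k or "
            f"the stride, or relax the mask")

    V = windows.vectors
    C = np.ascontiguousarray(V[cidx])
    cn = (C.astype(np.float64) ** 2).sum(axis=1)
    nbr = np.empty((qidx.size, k), dtype=np.int64)
    dist = np.empty((qidx.size, k))

    for c0 in range(0, qidx.size, chunk):
        sl = slice(c0, min(c0 + chunk, qidx.size))
        qi = qidx[sl]
        Q = np.ascontiguousarray(V[qi])
        qn = (Q.astype(np.float64) ** 2).sum(axis=1)
        G = Q @ C.T
        sel, n_less, kth, tol, need = select_k_rows(
            G, cn, qn, lo[sl], hi[sl], k, _TIE_RTOL, _TIE_ATOL)
        for r in np.flatnonzero(need):
            # more candidates tied at the k-th distance than free slots:
            # fill the remainder by a seeded uniform draw among the ties
            v = cn - 2.0 * G[r].astype(np.float64)
            v[lo[c0 + r]:hi[c0 + r]] = np.inf
            ties = np.flatnonzero(np.abs(v - kth[r]) <= tol[r])
            rng = np.random.default_rng((tie_seed, int(qidx[c0 + r])))
            sel[r, n_less[r]:] = rng.choice(ties, size=k - n_less[r],
                                            replace=False)
        vsel = cn[sel] - 2.0 * np.take_along_axis(
            G, sel, axis=1).astype(np.float64)
        d2 = np.maximum(vsel + qn[:, None], 0.0)
        order = np.argsort(d2, axis=1, kind="stable")
        nbr[sl] = cidx[np.take_along_axis(sel, order, axis=1)]
        dist[sl] = np.sqrt(np.take_along_axis(d2, order, axis=1))

    return NeighborTable(
        query_indices=qidx, neighbor_indices=nbr, distances=dist,
        query_starts=windows.starts[qidx],
        neighbor_starts=windows.starts[nbr],
        window_length=windows.length, k=k, exclusion_halfwidth=excl,
        tie_seed=tie_seed)


def reconstruct(neighbors: NeighborTable, stimulus: Spectrogram,
                lags: tuple = DEFAULT_LAGS) -> DecodedStimulus:
    """Average the stimulus segments behind each query's k nearest patterns.

    For every query at time t and every lag g, the segments
    stimulus[w+g : w+g+length] of the k neighbor windows (start w) are
    averaged and placed at [t+g : t+g+length]; overlapping placements and
    lags are averaged pixelwise with uniform weights. Neighbor segments
    falling outside the stimulus are dropped from their query's average.
    """
    if not lags:
        raise ValueError("empty lags")
    dt = stimulus.dt
    L = int(round(neighbors.window_length / dt))
    if L < 1:
        raise ValueError("window shorter than one stimulus time bin")
    n_f, n_time = stimulus.energy.shape
    energy_t = np.ascontiguousarray(stimulus.energy.T)
    nb = np.round(neighbors.neighbor_starts / dt).astype(np.int64)
    qb = np.round(neighbors.query_starts / dt).astype(np.int64)
    lag_bins = np.array([int(round(g / dt)) for g in lags], dtype=np.int64)

    acc_t = np.zeros_like(energy_t)
    cov = np.zeros(n_time, dtype=np.int64)
    n_dropped = int(accumulate_reconstruction(energy_t, nb, qb, lag_bins, L,
                                              acc_t, cov))
    covered = cov > 0
    predicted = np.full((n_f, n_time), np.nan)
    predicted[:, covered] = acc_t[covered].T / cov[covered]
    return DecodedStimulus(predicted=predicted, coverage=cov,
                           lags=tuple(lags), dt=dt, n_dropped_segments=n_dropped)


def _columnwise_corr(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Pearson r per column; NaN where either column has zero variance."""
    a = a - a.mean(axis=0)
    b = b - b.mean(axis=0)
    num = (a * b).sum(axis=0)
    den = np.sqrt((a * a).sum(axis=0) * (b * b).sum(axis=0))
    with np.errstate(invalid="ignore", divide="ignore"):
        r = np.where(den > 0, num / np.where(den > 0, den, 1.0), np.nan)
    return np.clip(r, -1.0, 1.0)


def score(actual: Spectrogram, decoded: DecodedStimulus) -> DecodingResult:
    """Score a reconstruction: NCR = log10 |Pearson r| over covered pixels,
    plus the per-time (across frequency) and per-frequency (across time)
    correlation profiles."""
    covered = decoded.coverage > 0
    if not covered.any():
        raise ValueError("empty coverage: nothing was reconstructed")
    A = actual.energy[:, covered]
    P = decoded.predicted[:, covered]
    a = A.ravel() - A.mean()
    p = P.ravel() - P.mean()
    den = math.sqrt(float(a @ a) * float(p @ p))
    if den == 0.0 or np.ptp(A) == 0 or np.ptp(P) == 0:
        corr_signed, ncr = float("nan"), float("-inf")
    else:
        corr_signed = float(np.clip((a @ p) / den, -1.0, 1.0))
        ncr = math.log10(abs(corr_signed)) if corr_signed != 0 else float("-inf")
    corr_t = np.full(decoded.coverage.size, np.nan)
    corr_t[covered] = _columnwise_corr(A, P)
    corr_f = _columnwise_corr(A.T, P.T)
    return DecodingResult(ncr=ncr, corr_signed=corr_signed, corr_t=corr_t,
                          corr_f=corr_f, dt=decoded.dt, lags=decoded.lags,
                          decoded=decoded)


def _query_grid(windows: WindowSet, eval_stride: float) -> np.ndarray:
    ratio = eval_stride / windows.stride
    if abs(ratio - round(ratio)) > 1e-9 or round(ratio) < 1:
        raise ValueError("eval_stride must be an integer multiple of stride")
    return np.arange(0, windows.n_windows, int(round(ratio)))


def _resolve_mask(windows: WindowSet, mask, mask_roles) -> WindowMask | None:
    if mask is None:
        return None
    if isinstance(mask, WindowMask):
        if mask.flags.size != windows.n_windows:
            raise ValueError("mask does not match the window grid")
        return mask
    return make_mask(windows, mask, roles=mask_roles)


def decode(units: list, stimulus: Spectrogram, code_kind: str = "temporal",
           *, k: int = 100, window_length: float = 0.100,
           stride: float = 0.010, eval_stride: float = 0.050,
           lags: tuple = DEFAULT_LAGS, exclusion_halfwidth: float | None = None,
           tie_seed: int = 0, mask=None, mask_roles: dict | None = None,
           bin_dt: float = 5e-4, hann_len: float = 9e-3,
           windows: WindowSet | None = None) -> DecodingResult:
    """Full decoding pipeline: windows -> nearest patterns -> reconstruction
    -> NCR score.

    Candidate windows step at ``stride`` (10 ms default); queries are
    evaluated on the coarser ``eval_stride`` grid (50 ms default). ``mask``
    may be a WindowMask or one of 'silence' / 'spiking' / 'combinatorial'
    (the latter with ``mask_roles``); a mask restricts both the query and
    the candidate pools.
    """
    if not lags:
        raise ValueError("empty lags")
    if windows is None:
        windows = make_windows(units, code_kind, length=window_length,
                               stride=stride, bin_dt=bin_dt, hann_len=hann_len)
    wmask = _resolve_mask(windows, mask, mask_roles)
    qgrid = _query_grid(windows, eval_stride)
    if wmask is None:
        q_idx, c_idx = qgrid, None
        mask_kind = "full"
    else:
        c_idx = np.flatnonzero(wmask.flags)
        q_idx = qgrid[wmask.flags[qgrid]]
        mask_kind = wmask.kind
        if q_idx.size == 0:
            raise CapacityError(f"mask '{mask_kind}' selects no query windows")
    nbrs = find_neighbors(windows, k=k,
                          exclusion_halfwidth=exclusion_halfwidth,
                          tie_seed=tie_seed, query_indices=q_idx,
                          candidate_indices=c_idx)
    dec = reconstruct(nbrs, stimulus, lags=lags)
    res = score(stimulus, dec)
    return DecodingResult(
        ncr=res.ncr, corr_signed=res.corr_signed, corr_t=res.corr_t,
        corr_f=res.corr_f, dt=res.dt, code_kind=windows.code_kind,
        window_length=windows.length, stride=windows.stride,
        eval_stride=eval_stride, lags=tuple(lags), mask_kind=mask_kind,
        k=k, decoded=dec)


def scan_lags(units: list, stimulus: Spectrogram, code_kind: str = "temporal",
              delays: tuple = tuple(np.round(np.arange(0.0, 0.0501, 0.005), 4)),
              **params):
    """NCR as a function of the stimulus-to-response delay.

    ``delays`` are positive delays d (stimulus preceding the response);
    each is decoded with the single lag -d. Returns ``(ncr_by_delay,
    best_delay)`` with ties resolved toward the smallest delay.
    """
    delays = tuple(delays)
    if not delays:
        raise ValueError("empty delay grid")
    # neighbors do not depend on the lag: search once, re-reconstruct per lag
    windows = make_windows(units, code_kind,
                           length=params.get("window_length", 0.100),
                           stride=params.get("stride", 0.010),
                           bin_dt=params.get("bin_dt", 5e-4),
                           hann_len=params.get("hann_len", 9e-3))
    qgrid = _query_grid(windows, params.get("eval_stride", 0.050))
    nbrs = find_neighbors(windows, k=params.get("k", 100),
                          exclusion_halfwidth=params.get("exclusion_halfwidth"),
                          tie_seed=params.get("tie_seed", 0),
                          query_indices=qgrid)
    ncr_by_delay = {}
    best_delay, best_ncr = None, -np.inf
    for d in sorted(delays):
        res = score(stimulus, reconstruct(nbrs, stimulus, lags=(-d,)))
        ncr_by_delay[d] = res.ncr
        if best_delay is None or res.ncr > best_ncr:
            best_delay, best_ncr = d, res.ncr
    return ncr_by_delay, best_delay


def scan_window_sizes(units: list, stimulus: Spectrogram,
                      code_kind: str = "temporal",
                      sizes: tuple = DEFAULT_WINDOW_SIZES, **params):
    """NCR as a function of the analysis window size (one decode per size)."""
    sizes = tuple(sizes)
    if not sizes:
        raise ValueError("empty sizes")
    duration = units[0].duration
    for s in sizes:
        if s <= 0 or s > duration:
            raise ValueError(f"window size {s}s outside (0, duration]")
    return {s: decode(units, stimulus, code_kind, window_length=s,
                      **params).ncr for s in sizes}


def calibrate_null(stimulus: Spectrogram, rates=(2.0, 40.0),
                   n_trains: int = 100, percentile: float = 95.0,
                   seed: int = 0, code_kinds=("temporal", "rate"),
                   **params) -> NullCalibration:
    """Null NCR distribution from homogeneous Poisson surrogate trains.

    ``n_trains`` Poisson units are simulated (rates taken verbatim when
    ``len(rates) == n_trains``, otherwise sampled log-uniformly between
    min(rates) and max(rates)), each decoded under every code kind against
    the stimulus, and the significance threshold is the stated percentile of
    the pooled NCR samples.
    """
    if n_trains < 1:
        raise ValueError("n_trains must be >= 1")
    rates = np.asarray(rates, dtype=float)
    if np.any(rates <= 0):
        raise ValueError("rates must be positive")
    rng = np.random.default_rng(seed)
    if rates.size != n_trains:
        rates = np.exp(rng.uniform(np.log(rates.min()), np.log(rates.max()),
                                   size=n_trains))
    samples = {ck: np.empty(n_trains) for ck in code_kinds}
    for i, rate in enumerate(rates):
        train = simulate_poisson(rate, stimulus.duration,
                                 seed=int(rng.integers(2 ** 31)),
                                 unit_id=f"null{i}")
        for ck in code_kinds:
            res = decode([train], stimulus, ck, tie_seed=seed + i, **params)
            samples[ck][i] = res.ncr
    pooled = np.concatenate(list(samples.values()))
    finite = pooled[np.isfinite(pooled)]
    threshold = float(np.percentile(finite, percentile))
    return NullCalibration(samples=samples, rates=rates, n_trains=n_trains,
                           percentile=percentile, threshold=threshold,
                           seed=seed, params=dict(params))
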