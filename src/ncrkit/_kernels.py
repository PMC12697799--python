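"""Numba kernels for the decoder's hot loops.

The nearest-pattern search ranks candidates by squared Euclidean distance
||q||^2 + ||c||^2 - 2 q.c; since ||q||^2 is constant per query, selection
works on v = ||c||^2 - 2 q.c. A per-row max-heap of size k finds the k-th
smallest in one pass; a second pass writes the strictly-smaller indices and
counts ties at the k-th value so the caller can resolve them with a seeded
draw.
"""

from __future__ import annotations

import numba
import numpy as np

__all__ = ["select_k_rows", "accumulate_reconstruction"]


@numba.njit(cache=True)
def _sift_down(heap_v, heap_i, size, root):
    while True:
        child = 2 * root + 1
        if child >= size:
            break
        if child + 1 < size and heap_v[child + 1] > heap_v[child]:
            child += 1
        if heap_v[child] <= heap_v[root]:
            break
        heap_v[root], heap_v[child] = heap_v[child], heap_v[root]
        heap_i[root], heap_i[child] = heap_i[child], heap_i[root]
        root = child


@numba.njit(cache=True)
def select_k_rows(G, cn, qn, lo, hi, k, rtol, atol):
    """Per-row k-smallest selection with tie bookkeeping.

    G : (nq, nc) float32, the query-candidate inner products.
    cn, qn : squared norms of candidates / queries.
    lo, hi : per-row exclusion range [lo, hi) of candidate columns.

    Returns (nbr, n_less, kth, tol, need_sampling): ``nbr[r, :n_less[r]]``
    holds the strictly-closer indices in ascending column order; rows with
    ``need_sampling`` False are completely filled (k - n_less tied indices
    appended in ascending order); rows with True have more ties at the k-th
    distance than free slots and need a seeded draw by the caller.
    """
    nq, nc = G.shape
    nbr = np.full((nq, k), -1, dtype=np.int64)
    n_less = np.zeros(nq, dtype=np.int64)
    kth = np.empty(nq, dtype=np.float64)
    tol_out = np.empty(nq, dtype=np.float64)
    need_sampling = np.zeros(nq, dtype=np.bool_)
    heap_v = np.empty(k, dtype=np.float64)
    heap_i = np.empty(k, dtype=np.int64)
    for r in range(nq):
        filled = 0
        for c in range(nc):
            if lo[r] <= c < hi[r]:
                continue
            v = cn[c] - 2.0 * G[r, c]
            if filled < k:
                heap_v[filled] = v
                heap_i[filled] = c
                filled += 1
                if filled == k:
                    for root in range(k // 2 - 1, -1, -1):
                        _sift_down(heap_v, heap_i, k, root)
            elif v < heap_v[0]:
                heap_v[0] = v
                heap_i[0] = c
                _sift_down(heap_v, heap_i, k, 0)
        kv = heap_v[0]
        # tolerance on the squared-distance scale (kv + qn >= 0)
        tol = rtol * max(kv + qn[r], 0.0) + atol
        kth[r] = kv
        tol_out[r] = tol
        nl = 0
        nt = 0
        for c in range(nc):
            if lo[r] <= c < hi[r]:
                continue
            v = cn[c] - 2.0 * G[r, c]
            if v < kv - tol:
                nbr[r, nl] = c
                nl += 1
            elif abs(v - kv) <= tol:
                nt += 1
        n_less[r] = nl
        if nt > k - nl:
            need_sampling[r] = True
        else:
            pos = nl
            for c in range(nc):
                if lo[r] <= c < hi[r]:
                    continue
                v = cn[c] - 2.0 * G[r, c]
                if abs(v - kv) <= tol:
                    nbr[r, pos] = c
                    pos += 1
    return nbr, n_less, kth, tol_out, need_sampling


@numba.njit(cache=True)
def accumulate_reconstruction(energy_t, nbr_bins, q_bins, lag_bins, length,
                              acc_t, cov):
    """Accumulate per-query neighbor-segment averages into the stimulus grid.

    energy_t : (n_time, n_channels) stimulus energy, time-major for locality.
    nbr_bins : (nq, k) neighbor window start bins.
    q_bins : (nq,) query window start bins.
    lag_bins : integer lag shifts in stimulus bins.
    acc_t, cov : accumulators, (n_time, n_channels) and (n_time,).

    Returns the number of neighbor segments dropped at the stimulus edges.
    """
    n_time, n_f = energy_t.shape
    nq, k = nbr_bins.shape
    pred = np.empty((length, n_f))
    n_dropped = 0
    for g in lag_bins:
        for q in range(nq):
            nv = 0
            pred[:, :] = 0.0
            for j in range(k):
                s = nbr_bins[q, j] + g
                if 0 <= s <= n_time - length:
                    nv += 1
                    for t in range(length):
                        row = energy_t[s + t]
                        for f in range(n_f):
                            pred[t, f] += row[f]
                else:
                    n_dropped += 1
            p = q_bins[q] + g
            if nv > 0 and 0 <= p <= n_time - length:
                inv = 1.0 / nv
                for t in range(length):
                    for f in range(n_f):
                        acc_t[p + t, f] += pred[t, f] * inv
                    cov[p + t] += 1
    return n_dropped
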