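"""Numba kernels for synchronization-likelihood recurrence computation.

The expensive inner loops live here: building per-channel recurrence hit
sets (for every reference embedding vector, the k nearest candidate
vectors inside the Theiler/outer window) and counting joint recurrences
for channel pairs via bit-packed masks. Everything is exact and
deterministic; ties at the k-th distance are broken by ascending partner
time so the optimized path agrees bit-for-bit with a brute-force oracle.
"""

from __future__ import annotations

import numpy as np
from numba import njit

_U64 = np.uint64


@njit(cache=True, inline="always")
def _popcount64(x):
    x = x - ((x >> _U64(1)) & _U64(0x5555555555555555))
    x = (x & _U64(0x3333333333333333)) + ((x >> _U64(2)) & _U64(0x3333333333333333))
    x = (x + (x >> _U64(4))) & _U64(0x0F0F0F0F0F0F0F0F)
    return (x * _U64(0x0101010101010101)) >> _U64(56)


@njit(cache=True)
def _round_half_up(x):
    return int(np.floor(x + 0.5))


@njit(cache=True)
def channel_hits(V, times, total_T, w1, w2, p_ref, chebyshev):
    """Recurrence hit sets for one channel's embedding.

    Parameters
    ----------
    V : (N, m) float64
        Time-delay embedding vectors.
    times : (N,) int64
        Global sample time of each vector (epoch-concatenated grid; gaps
        where vectors would span an epoch boundary).
    total_T : int
        Extent of the global time grid.
    w1, w2 : int
        Theiler and outer windows: candidates j satisfy w1 < |t_i-t_j| < w2.
    p_ref : float
        Target recurrence probability; k_i = max(1, round(p_ref * n_cand_i)).
    chebyshev : bool
        Use the Chebyshev metric instead of (squared) Euclidean.

    Returns
    -------
    hits : (N, n_words) uint64
        Bit mask over candidate offsets; bit ``oi`` of row i set iff the
        candidate at offset index ``oi`` is among the k_i nearest.
    kvec : (N,) int64
        Realized recurrence count k_i (0 where a row has no candidates).
    """
    N, m = V.shape
    B = w2 - w1 - 1  # offsets per side
    width = 2 * B
    n_words = (width + 63) // 64

    time2idx = np.full(total_T, -1, dtype=np.int64)
    for i in range(N):
        time2idx[times[i]] = i

    hits = np.zeros((N, n_words), dtype=np.uint64)
    kvec = np.zeros(N, dtype=np.int64)
    d = np.empty(width, dtype=np.float64)

    for i in range(N):
        ti = times[i]
        n_cand = 0
        for oi in range(width):
            if oi < B:
                off = oi - (w2 - 1)
            else:
                off = (w1 + 1) + (oi - B)
            tj = ti + off
            dist = np.inf
            if 0 <= tj < total_T:
                j = time2idx[tj]
                if j >= 0:
                    if chebyshev:
                        dist = 0.0
                        for a in range(m):
                            diff = abs(V[i, a] - V[j, a])
                            if diff > dist:
                                dist = diff
                    else:
                        dist = 0.0
                        for a in range(m):
                            diff = V[i, a] - V[j, a]
                            dist += diff * diff
                    n_cand += 1
            d[oi] = dist
        if n_cand == 0:
            continue
        k = _round_half_up(p_ref * n_cand)
        if k < 1:
            k = 1
        if k > n_cand:
            k = n_cand
        kth = np.partition(d.copy(), k - 1)[k - 1]
        cnt = 0
        for oi in range(width):
            if d[oi] < kth:
                hits[i, oi >> 6] |= _U64(1) << _U64(oi & 63)
                cnt += 1
        # ties at the k-th distance: admit by ascending partner time
        for oi in range(width):
            if cnt >= k:
                break
            if d[oi] == kth:
                hits[i, oi >> 6] |= _U64(1) << _U64(oi & 63)
                cnt += 1
        kvec[i] = k
    return hits, kvec


@njit(cache=True)
def pair_sl(hits_a, hits_b, kvec):
    """Average joint-recurrence fraction of two channels' hit sets.

    For each reference i the instantaneous value is
    ``|hits_a(i) & hits_b(i)| / k_i``; the returned SL is the mean over
    references with at least one candidate.
    """
    N, n_words = hits_a.shape
    total = 0.0
    used = 0
    for i in range(N):
        k = kvec[i]
        if k == 0:
            continue
        c = _U64(0)
        for w in range(n_words):
            c += _popcount64(hits_a[i, w] & hits_b[i, w])
        total += c / k
        used += 1
    if used == 0:
        return np.nan
    return total / used
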