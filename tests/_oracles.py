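"""Independent brute-force oracles for the optimized implementations.

Everything here is written as directly as possible from the definitions
(double loops, exhaustive path enumeration, Floyd-Warshall triple loop)
and deliberately shares no code with the package internals, so agreement
is evidence of correctness rather than of shared bugs.
"""

from __future__ import annotations

import itertools

import numpy as np


# ---------------------------------------------------------------------------
# synchronization likelihood


def brute_force_sl(x: np.ndarray, y: np.ndarray, lag: int, dim: int,
                   w1: int, w2: int, p_ref: float) -> float:
    """Literal double-loop SL of two (epochs x samples) series.

    For every reference vector: collect candidates in the window, take the
    k = max(1, round(p_ref * n_cand)) nearest (ties by ascending partner
    time), and count how many of one channel's recurrences the other
    channel shares.
    """

    def embed(sig):
        n_ep, n_samp = sig.shape
        vecs, times = [], []
        for e in range(n_ep):
            for t0 in range(n_samp - (dim - 1) * lag):
                vecs.append([sig[e, t0 + a * lag] for a in range(dim)])
                times.append(e * n_samp + t0)
        return np.array(vecs), np.array(times)

    def hit_sets(sig):
        vecs, times = embed(sig)
        hits, ks = [], []
        for i in range(len(vecs)):
            cand = [j for j in range(len(vecs))
                    if w1 < abs(times[i] - times[j]) < w2]
            if not cand:
                hits.append(set())
                ks.append(0)
                continue
            k = max(1, int(np.floor(p_ref * len(cand) + 0.5)))
            d2 = [float(((vecs[i] - vecs[j]) ** 2).sum()) for j in cand]
            order = sorted(range(len(cand)), key=lambda q: (d2[q], times[cand[q]]))
            hits.append({cand[q] for q in order[:k]})
            ks.append(k)
        return hits, ks

    hx, ks = hit_sets(x)
    hy, _ = hit_sets(y)
    vals = [len(a & b) / k for a, b, k in zip(hx, hy, ks) if k > 0]
    return float(np.mean(vals))


# ---------------------------------------------------------------------------
# graph metrics


def oracle_clustering(W: np.ndarray) -> float:
    """Geometric-mean weighted clustering on the raw weights."""
    n = W.shape[0]
    Wn = W
    cs = []
    for i in range(n):
        nbrs = [j for j in range(n) if W[i, j] > 0]
        k = len(nbrs)
        if k < 2:
            cs.append(0.0)
            continue
        tri = 0.0
        for j, h in itertools.combinations(nbrs, 2):
            if W[j, h] > 0:
                tri += (Wn[i, j] * Wn[i, h] * Wn[j, h]) ** (1.0 / 3.0)
        cs.append(2.0 * tri / (k * (k - 1)))
    return float(np.mean(cs))


def oracle_distances(W: np.ndarray) -> np.ndarray:
    """Floyd-Warshall on lengths 1/w."""
    n = W.shape[0]
    D = np.full((n, n), np.inf)
    np.fill_diagonal(D, 0.0)
    for i in range(n):
        for j in range(n):
            if W[i, j] > 0:
                D[i, j] = 1.0 / W[i, j]
    for k in range(n):
        for i in range(n):
            for j in range(n):
                if D[i, k] + D[k, j] < D[i, j]:
                    D[i, j] = D[i, k] + D[k, j]
    return D


def _components(W: np.ndarray) -> list[set[int]]:
    n = W.shape[0]
    seen, comps = set(), []
    for s in range(n):
        if s in seen:
            continue
        comp, stack = {s}, [s]
        while stack:
            u = stack.pop()
            for v in range(n):
                if W[u, v] > 0 and v not in comp:
                    comp.add(v)
                    stack.append(v)
        seen |= comp
        comps.append(comp)
    return comps


def oracle_global(W: np.ndarray) -> tuple[float, float, float]:
    """(C, L, Eg): L over the largest component, Eg over all pairs."""
    n = W.shape[0]
    D = oracle_distances(W)
    inv = [1.0 / D[i, j] if np.isfinite(D[i, j]) else 0.0
           for i in range(n) for j in range(n) if i != j]
    Eg = float(np.mean(inv))
    comp = max(_components(W), key=len)
    nodes = sorted(comp)
    ls = [D[i, j] for i in nodes for j in nodes if i != j]
    return oracle_clustering(W), float(np.mean(ls)), Eg


def oracle_betweenness(W: np.ndarray, tol: float = 1e-12) -> np.ndarray:
    """Fractional shortest-path counts via exhaustive path enumeration."""
    n = W.shape[0]
    b = np.zeros(n)
    for s, t in itertools.combinations(range(n), 2):
        best, paths = np.inf, []
        for k in range(n):
            for mid in itertools.permutations([v for v in range(n) if v not in (s, t)], k):
                path = (s, *mid, t)
                length = 0.0
                ok = True
                for u, v in zip(path[:-1], path[1:]):
                    if W[u, v] == 0:
                        ok = False
                        break
                    length += 1.0 / W[u, v]
                if not ok:
                    continue
                if length < best - tol:
                    best, paths = length, [path]
                elif abs(length - best) <= tol:
                    paths.append(path)
        if not paths:
            continue
        for v in range(n):
            if v in (s, t):
                continue
            through = sum(1 for p in paths if v in p)
            b[v] += through / len(paths)
    return b


def oracle_local_efficiency(W: np.ndarray) -> np.ndarray:
    n = W.shape[0]
    out = np.zeros(n)
    for i in range(n):
        nbrs = [j for j in range(n) if W[i, j] > 0]
        if len(nbrs) < 2:
            continue
        sub = W[np.ix_(nbrs, nbrs)]
        D = oracle_distances(sub)
        vals = [1.0 / D[a, b] if np.isfinite(D[a, b]) else 0.0
                for a in range(len(nbrs)) for b in range(len(nbrs)) if a != b]
        out[i] = float(np.mean(vals))
    return out


def oracle_strength(W: np.ndarray) -> np.ndarray:
    return W.sum(axis=0)


def oracle_chi2(table: np.ndarray) -> float:
    """Closed form sum (O-E)^2 / E for a contingency table."""
    table = np.asarray(table, dtype=float)
    row = table.sum(axis=1, keepdims=True)
    col = table.sum(axis=0, keepdims=True)
    E = row @ col / table.sum()
    return float(((table - E) ** 2 / E).sum())
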