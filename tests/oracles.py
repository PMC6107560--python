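"""Independent brute-force oracles used by the test suite.

These deliberately avoid the implementation's dynamic programs: DTW is
checked by exhaustive enumeration of monotone warping paths, the simple
ratio index by explicit event-by-event counting, and percentiles by direct
sort-and-interpolate.
"""

import numpy as np
from scipy.spatial.distance import cdist


def enumerate_warping_paths(n, m):
    """All monotone boundary-matched paths through an n x m grid."""
    paths = []

    def walk(i, j, path):
        if i == n - 1 and j == m - 1:
            paths.append(list(path))
            return
        for di, dj in ((1, 1), (1, 0), (0, 1)):
            ni, nj = i + di, j + dj
            if ni < n and nj < m:
                path.append((ni, nj))
                walk(ni, nj, path)
                path.pop()

    walk(0, 0, [(0, 0)])
    return paths


def brute_force_dtw(a, b):
    """(min cost, set of path lengths attaining the min) by full enumeration."""
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    a = a[:, None] if a.ndim == 1 else a
    b = b[:, None] if b.ndim == 1 else b
    cost = cdist(a, b)
    best = np.inf
    lengths = set()
    for path in enumerate_warping_paths(len(a), len(b)):
        c = sum(cost[i, j] for i, j in path)
        if c < best - 1e-12:
            best = c
            lengths = {len(path)}
        elif abs(c - best) <= 1e-12:
            lengths.add(len(path))
    return best, lengths


def brute_force_motif_alignment(cost):
    """(min accumulated cost, lengths of paths attaining it) over all monotone
    element alignments; the normalized motif score is min_cost / length."""
    n, m = cost.shape
    best = np.inf
    lengths = set()
    for path in enumerate_warping_paths(n, m):
        c = sum(cost[i, j] for i, j in path)
        if c < best - 1e-12:
            best = c
            lengths = {len(path)}
        elif abs(c - best) <= 1e-12:
            lengths.add(len(path))
    return best, lengths


def brute_force_sri(G):
    """SRI by explicit dyad/event counting on a binary events x birds array."""
    G = np.asarray(G)
    n = G.shape[1]
    S = np.zeros((n, n))
    for i in range(n):
        for j in range(n):
            if i == j:
                continue
            x = yi = yj = 0
            for row in G:
                if row[i] and row[j]:
                    x += 1
                elif row[i]:
                    yi += 1
                elif row[j]:
                    yj += 1
            denom = x + yi + yj
            S[i, j] = x / denom if denom else 0.0
    return S


def interpolated_percentile(values, q):
    """Linear-interpolation percentile (the numpy default), written directly."""
    v = sorted(values)
    h = (len(v) - 1) * (q / 100.0)
    lo = int(np.floor(h))
    hi = min(lo + 1, len(v) - 1)
    return v[lo] + (h - lo) * (v[hi] - v[lo])
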