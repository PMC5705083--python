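"""Independent, deliberately naive reference implementations.

Everything here is written with explicit loops straight from the printed
definitions, independent of the vectorized production code, to serve as
oracles in tests.
"""

from __future__ import annotations

import itertools
import math

import numpy as np


# -- generalized distance correlation (loop-based) --------------------------


def naive_distance_matrix(values, scale, levels=None):
    """Per-type sample-sample distances, one pair at a time."""
    n = len(values)
    out = [[0.0] * n for _ in range(n)]
    if scale == "quantitative":
        vals = [float(v) for v in values]
        for i in range(n):
            for j in range(n):
                out[i][j] = abs(vals[i] - vals[j])
    elif scale == "ordinal":
        codes = [levels.index(str(v)) for v in values]
        ranks = []
        for c in codes:
            smaller = sum(1 for d in codes if d < c)
            equal = sum(1 for d in codes if d == c)
            ranks.append(smaller + (equal + 1) / 2.0)  # midrank
        for i in range(n):
            for j in range(n):
                out[i][j] = abs(ranks[i] - ranks[j])
    else:
        for i in range(n):
            for j in range(n):
                out[i][j] = 0.0 if str(values[i]) == str(values[j]) else 1.0
    return np.array(out)


def naive_star(d):
    """Modified matrix A* from the printed definition, looped."""
    d = np.asarray(d, dtype=float)
    n = d.shape[0]
    rowmeans = [sum(d[i][j] for j in range(n)) / n for i in range(n)]
    grand = sum(d[i][j] for i in range(n) for j in range(n)) / n**2
    a = [[0.0] * n for _ in range(n)]
    for i in range(n):
        for j in range(n):
            if i != j:
                centered = d[i][j] - rowmeans[i] - rowmeans[j] + grand
                a[i][j] = (n / (n - 1)) * (centered - d[i][j] / n)
            else:
                a[i][j] = (n / (n - 1)) * (rowmeans[i] - grand)
    return np.array(a)


def naive_ucov(dk, dl):
    """Bias-corrected squared distance covariance, looped."""
    n = len(dk)
    astar = naive_star(dk)
    bstar = naive_star(dl)
    total = sum(astar[i][j] * bstar[i][j] for i in range(n) for j in range(n))
    diag = sum(astar[i][i] * bstar[i][i] for i in range(n))
    return ((n - 3) / n) * (total - (n / (n - 2)) * diag)


def naive_dcor(dk, dl):
    """Generalized distance correlation, looped."""
    ukl = naive_ucov(dk, dl)
    ukk = naive_ucov(dk, dk)
    ull = naive_ucov(dl, dl)
    if ukk <= 1e-12 or ull <= 1e-12:
        return 0.0
    return math.copysign(math.sqrt(abs(ukl)), ukl) / (ukk * ull) ** 0.25


# -- Goodman-Kruskal gamma by pair enumeration ------------------------------


def naive_gamma(x, y):
    """Gamma over all observation pairs, enumerated."""
    n = len(x)
    n_c = n_d = 0
    for i in range(n):
        for j in range(i + 1, n):
            prod = (x[i] - x[j]) * (y[i] - y[j])
            if prod > 0:
                n_c += 1
            elif prod < 0:
                n_d += 1
    if n_c + n_d == 0:
        return 0.0
    return (n_c - n_d) / (n_c + n_d)


def naive_gamma_from_table(counts):
    """Gamma by enumerating cell pairs of a contingency table."""
    counts = np.asarray(counts, dtype=float)
    r, k = counts.shape
    n_c = n_d = 0.0
    for i in range(r):
        for j in range(k):
            for a in range(r):
                for b in range(k):
                    if a > i and b > j:
                        n_c += counts[i][j] * counts[a][b]
                    elif a > i and b < j:
                        n_d += counts[i][j] * counts[a][b]
    if n_c + n_d == 0:
        return 0.0
    return (n_c - n_d) / (n_c + n_d)


# -- greedy Ward oracle ------------------------------------------------------


def greedy_ward_two_clusters(points):
    """Agglomerate 1-D points by exact Ward criterion; return 2-cluster sets.

    At each step the merge minimizing the increase in total within-cluster
    sum of squares is taken (ties: lowest index pair).
    """
    clusters = [[i] for i in range(len(points))]
    points = np.asarray(points, dtype=float)

    def sse(idx):
        vals = points[idx]
        return float(((vals - vals.mean()) ** 2).sum())

    while len(clusters) > 2:
        best = None
        for a, b in itertools.combinations(range(len(clusters)), 2):
            delta = sse(clusters[a] + clusters[b]) - sse(clusters[a]) - sse(clusters[b])
            if best is None or delta < best[0] - 1e-12:
                best = (delta, a, b)
        _, a, b = best
        clusters = (
            [c for i, c in enumerate(clusters) if i not in (a, b)]
            + [clusters[a] + clusters[b]]
        )
    return [frozenset(c) for c in clusters]
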