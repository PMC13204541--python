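"""Independent brute-force oracles for graph metrics and statistics.

Everything here is written as plain loops from the definitions, kept
deliberately separate from the package implementation so the two can
disagree.  Only intended for small graphs (N <= ~10).
"""

from __future__ import annotations

import itertools
import math

import numpy as np


def bf_density(w):
    n = len(w)
    e = sum(1 for i in range(n) for j in range(i + 1, n) if w[i][j] > 0)
    return e / (n * (n - 1) / 2)


def bf_clustering(w):
    """Onnela per-node clustering by explicit triple enumeration."""
    n = len(w)
    out = []
    for i in range(n):
        nbrs = [j for j in range(n) if w[i][j] > 0]
        k = len(nbrs)
        if k < 2:
            out.append(0.0)
            continue
        s = 0.0
        for j in range(n):
            for h in range(n):
                s += (w[i][j] * w[i][h] * w[j][h]) ** (1 / 3)
        out.append(s / (k * (k - 1)))
    return np.array(out)


def bf_transitivity(w):
    n = len(w)
    num = 0.0
    den = 0.0
    for i in range(n):
        k = sum(1 for j in range(n) if w[i][j] > 0)
        den += k * (k - 1)
        for j in range(n):
            for h in range(n):
                num += (w[i][j] * w[i][h] * w[j][h]) ** (1 / 3)
    return num / den if den else float("nan")


def bf_distances(w):
    """Floyd-Warshall on lengths 1/w."""
    n = len(w)
    d = [[0.0 if i == j else (1.0 / w[i][j] if w[i][j] > 0 else math.inf)
          for j in range(n)] for i in range(n)]
    for k in range(n):
        for i in range(n):
            for j in range(n):
                if d[i][k] + d[k][j] < d[i][j]:
                    d[i][j] = d[i][k] + d[k][j]
    return d


def bf_path_length(w):
    d = bf_distances(w)
    n = len(w)
    vals = [d[i][j] for i in range(n) for j in range(n)
            if i != j and math.isfinite(d[i][j])]
    return sum(vals) / len(vals)


def bf_global_efficiency(w):
    d = bf_distances(w)
    n = len(w)
    vals = [1.0 / d[i][j] if math.isfinite(d[i][j]) else 0.0
            for i in range(n) for j in range(n) if i != j]
    return sum(vals) / len(vals)


def bf_local_efficiency(w):
    n = len(w)
    out = []
    for i in range(n):
        nbrs = [j for j in range(n) if w[i][j] > 0]
        if len(nbrs) < 2:
            out.append(0.0)
            continue
        sub = [[w[a][b] for b in nbrs] for a in nbrs]
        out.append(bf_global_efficiency(sub))
    return np.array(out)


def bf_assortativity(w):
    n = len(w)
    s = [sum(w[i]) for i in range(n)]
    xs, ys = [], []
    for i in range(n):
        for j in range(i + 1, n):
            if w[i][j] > 0:
                xs += [s[i], s[j]]
                ys += [s[j], s[i]]
    if len(xs) < 4:
        return float("nan")
    if len(set(xs)) == 1 or len(set(ys)) == 1:
        return float("nan")
    mx, my = np.mean(xs), np.mean(ys)
    cov = np.mean([(x - mx) * (y - my) for x, y in zip(xs, ys)])
    sx = math.sqrt(np.mean([(x - mx) ** 2 for x in xs]))
    sy = math.sqrt(np.mean([(y - my) ** 2 for y in ys]))
    if sx == 0 or sy == 0:
        return float("nan")
    return cov / (sx * sy)


def bf_rich_club(w, k):
    n = len(w)
    deg = [sum(1 for j in range(n) if w[i][j] > 0) for i in range(n)]
    club = [i for i in range(n) if deg[i] > k]
    if len(club) < 2:
        return float("nan")
    e = sum(1 for a, b in itertools.combinations(club, 2) if w[a][b] > 0)
    return 2 * e / (len(club) * (len(club) - 1))


def bf_bh(pvals):
    """Step-up BH adjusted p-values, the slow explicit way."""
    m = len(pvals)
    indexed = sorted(range(m), key=lambda i: pvals[i])
    adj = [0.0] * m
    prev = 1.0
    for rank_from_end, idx in enumerate(reversed(indexed)):
        rank = m - rank_from_end
        val = min(prev, pvals[idx] * m / rank)
        adj[idx] = val
        prev = val
    return adj


def bf_pooled_t(x, y):
    """Pooled two-sample t and two-sided p from the textbook formula."""
    from scipy import stats
    n1, n2 = len(x), len(y)
    m1, m2 = np.mean(x), np.mean(y)
    v1 = sum((a - m1) ** 2 for a in x) / (n1 - 1)
    v2 = sum((a - m2) ** 2 for a in y) / (n2 - 1)
    df = n1 + n2 - 2
    sp2 = ((n1 - 1) * v1 + (n2 - 1) * v2) / df
    t = (m1 - m2) / math.sqrt(sp2 * (1 / n1 + 1 / n2))
    p = 2 * stats.t.sf(abs(t), df)
    return t, df, p


def random_weighted_graph(rng, n, p_edge=0.5):
    """Random symmetric weighted graph with weights in (0, 1]."""
    w = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            if rng.random() < p_edge:
                w[i, j] = w[j, i] = rng.uniform(0.05, 1.0)
    return w
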