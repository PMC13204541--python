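"""Weighted graph-theory measures for brain networks.

All measures follow the conventions of the brain-connectivity-toolbox
family of implementations on undirected weighted graphs with weights in
[0, 1] and zero diagonal:

* clustering coefficient — Onnela geometric-mean-of-triangles form,
  ``C_i = [1/(k_i(k_i-1))] * sum_{j,h} (w_ij w_ih w_jh)^(1/3)``;
* transitivity — the global ratio form of the same triangle sum;
* shortest paths — edge length ``1/w``; characteristic path length is
  the mean distance over reachable ordered pairs;
* global efficiency — mean of ``1/d`` over ordered pairs (``1/inf = 0``);
* local efficiency — global efficiency of each node's neighbor-induced
  subgraph;
* assortativity — Pearson correlation of endpoint strengths over the
  edge list, each undirected edge contributing both orientations;
* rich club — edge density among nodes of (binary) degree > k;
* small-worldness — ``sigma = (C/C_rand)/(L/L_rand)`` against an
  ensemble of degree-preserving edge-swap surrogates with the weight
  multiset shuffled onto the rewired topology.

Statistically undefined quantities (assortativity at zero strength
variance, transitivity with no connected triple, rich club with fewer
than two members) are returned as NaN so cohort tables stay
rectangular; structural impossibilities (empty graph, N < 2) raise.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.sparse.csgraph import shortest_path as _sp_shortest_path

from .connectome import WeightedGraphView

__all__ = [
    "density",
    "clustering_weighted",
    "transitivity_weighted",
    "path_length",
    "global_efficiency",
    "local_efficiency",
    "assortativity",
    "rich_club",
    "rich_club_curve",
    "small_worldness",
    "ring_lattice_with_shortcuts",
    "SmallWorldResult",
    "NetworkMetricSet",
    "compute_metrics",
]


def _as_matrix(g) -> np.ndarray:
    if isinstance(g, WeightedGraphView):
        return g.weights
    w = np.asarray(g, dtype=float)
    if w.ndim != 2 or w.shape[0] != w.shape[1]:
        raise ValueError("expected a square weight matrix")
    return w


def density(g) -> float:
    """Fraction of possible edges present: E / (N(N-1)/2)."""
    w = _as_matrix(g)
    n = w.shape[0]
    if n < 2:
        raise ValueError("density requires at least 2 nodes")
    e = np.count_nonzero(np.triu(w, k=1))
    return e / (n * (n - 1) / 2)


def clustering_weighted(g) -> tuple[np.ndarray, float]:
    """Onnela weighted clustering coefficient per node, and its mean.

    Nodes of degree < 2 have C_i = 0 and are included in the mean.
    """
    w = _as_matrix(g)
    w3 = np.cbrt(w)
    cyc = np.diag(w3 @ w3 @ w3)  # sum over j,h of (w_ij w_ih w_jh)^{1/3}
    k = np.count_nonzero(w, axis=1).astype(float)
    denom = k * (k - 1)
    with np.errstate(divide="ignore", invalid="ignore"):
        c = np.where(denom > 0, cyc / np.where(denom > 0, denom, 1.0), 0.0)
    return c, float(c.mean())


def transitivity_weighted(g) -> float:
    """Global weighted transitivity: triangle sum over connected-triple count.

    NaN when no node has degree >= 2 (the 0/0 case).
    """
    w = _as_matrix(g)
    w3 = np.cbrt(w)
    num = float(np.trace(w3 @ w3 @ w3))
    k = np.count_nonzero(w, axis=1).astype(float)
    den = float((k * (k - 1)).sum())
    if den == 0:
        return float("nan")
    return num / den


def _distance_matrix(w: np.ndarray) -> np.ndarray:
    with np.errstate(divide="ignore"):
        lengths = np.where(w > 0, 1.0 / np.where(w > 0, w, 1.0), np.inf)
    np.fill_diagonal(lengths, 0.0)
    return _sp_shortest_path(lengths, method="D", directed=False)


def path_length(g, warn_disconnected: bool = True) -> float:
    """Characteristic path length with edge lengths 1/weight.

    Mean shortest-path distance over reachable ordered pairs;
    unreachable pairs are excluded (with a warning).  Raises if no pair
    is connected.
    """
    w = _as_matrix(g)
    d = _distance_matrix(w)
    off = ~np.eye(w.shape[0], dtype=bool)
    finite = np.isfinite(d) & off
    if not finite.any():
        raise ValueError("no connected pair: path length undefined")
    if (~np.isfinite(d) & off).any() and warn_disconnected:
        warnings.warn("graph is disconnected; unreachable pairs excluded from "
                      "characteristic path length", stacklevel=2)
    return float(d[finite].mean())


def global_efficiency(g) -> float:
    """Mean inverse shortest-path distance over ordered node pairs."""
    w = _as_matrix(g)
    n = w.shape[0]
    if n < 2:
        raise ValueError("global efficiency requires at least 2 nodes")
    d = _distance_matrix(w)
    off = ~np.eye(n, dtype=bool)
    with np.errstate(divide="ignore"):
        inv = np.where(np.isfinite(d) & (d > 0), 1.0 / np.where(d > 0, d, 1.0), 0.0)
    return float(inv[off].mean())


def local_efficiency(g) -> tuple[np.ndarray, float]:
    """Global efficiency of each node's neighbor-induced subgraph, and mean.

    Nodes with fewer than two neighbors score 0.
    """
    w = _as_matrix(g)
    n = w.shape[0]
    out = np.zeros(n)
    for i in range(n):
        nbrs = np.flatnonzero(w[i] > 0)
        if nbrs.size < 2:
            continue
        sub = w[np.ix_(nbrs, nbrs)]
        out[i] = global_efficiency(sub)
    return out, float(out.mean())


def assortativity(g) -> float:
    """Strength assortativity: Pearson correlation of endpoint strengths.

    Each undirected edge contributes both orientations.  NaN when the
    endpoint-strength variance is zero (e.g. regular graphs).
    """
    w = _as_matrix(g)
    iu, ju = np.triu_indices(w.shape[0], k=1)
    mask = w[iu, ju] > 0
    i, j = iu[mask], ju[mask]
    if i.size < 2:
        return float("nan")
    s = w.sum(axis=1)
    x = np.concatenate([s[i], s[j]])
    y = np.concatenate([s[j], s[i]])
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return float("nan")
    return float(np.corrcoef(x, y)[0, 1])


def rich_club(g, k: int) -> float:
    """Rich-club coefficient at degree level k on the binarized graph.

    ``phi(k) = 2 E_{>k} / (N_{>k}(N_{>k}-1))`` where N_{>k} counts nodes
    of degree strictly greater than k; NaN when fewer than two survive.
    """
    if k < 0:
        raise ValueError("degree level k must be >= 0")
    w = _as_matrix(g)
    a = (w > 0).astype(int)
    deg = a.sum(axis=1)
    sel = np.flatnonzero(deg > k)
    if sel.size < 2:
        return float("nan")
    sub = a[np.ix_(sel, sel)]
    e = sub.sum() / 2
    return float(2 * e / (sel.size * (sel.size - 1)))


def rich_club_curve(g) -> dict[int, float]:
    """Rich-club coefficient for every degree level 0 .. max degree - 1."""
    w = _as_matrix(g)
    deg = (w > 0).sum(axis=1)
    kmax = int(deg.max(initial=0))
    return {k: rich_club(w, k) for k in range(kmax)}


def _edge_list(a: np.ndarray) -> list[tuple[int, int]]:
    iu, ju = np.triu_indices(a.shape[0], k=1)
    mask = a[iu, ju] > 0
    return list(zip(iu[mask].tolist(), ju[mask].tolist()))


def _rewire_degree_preserving(a: np.ndarray, swaps_per_edge: int,
                              rng: np.random.Generator) -> np.ndarray:
    """Maslov-Sneppen double edge swaps on a binary symmetric matrix.

    Attempts ``swaps_per_edge * E`` swaps; proposals creating self-loops,
    multi-edges, or duplicating existing edges are rejected.  Rigid
    graphs (e.g. complete) are returned unchanged.
    """
    a = a.copy()
    edges = _edge_list(a)
    n_edges = len(edges)
    if n_edges < 2:
        return a
    attempts = swaps_per_edge * n_edges
    for _ in range(attempts):
        e1, e2 = rng.choice(n_edges, size=2, replace=False)
        (u, v), (x, y) = edges[e1], edges[e2]
        if rng.random() < 0.5:
            x, y = y, x
        # propose (u, x), (v, y)
        if u == x or v == y:
            continue
        if a[u, x] or a[v, y]:
            continue
        a[u, v] = a[v, u] = 0
        a[x, y] = a[y, x] = 0
        a[u, x] = a[x, u] = 1
        a[v, y] = a[y, v] = 1
        edges[e1] = (min(u, x), max(u, x))
        edges[e2] = (min(v, y), max(v, y))
    return a


def ring_lattice_with_shortcuts(n: int = 36, k: int = 4, shortcut_frac: float = 0.1,
                                seed: int | None = None) -> np.ndarray:
    """Watts-Strogatz-style substrate: a ring lattice with rewired shortcuts.

    Each node connects to its ``k`` nearest ring neighbors; a fraction of
    edges is then rewired to random shortcuts (keeping the edge count).
    With unit weights this graph keeps high clustering while the
    shortcuts shorten paths — the canonical small-world construction.
    """
    if k % 2 or k < 2:
        raise ValueError("k must be even and >= 2")
    rng = np.random.default_rng(seed)
    w = np.zeros((n, n))
    for i in range(n):
        for d in range(1, k // 2 + 1):
            j = (i + d) % n
            w[i, j] = w[j, i] = 1.0
    edges = _edge_list(w)
    n_rewire = max(1, int(round(shortcut_frac * len(edges))))
    for idx in rng.choice(len(edges), size=n_rewire, replace=False):
        i, j = edges[idx]
        for _ in range(100):
            a, b = rng.integers(0, n, 2)
            if a != b and w[a, b] == 0:
                w[i, j] = w[j, i] = 0.0
                w[a, b] = w[b, a] = 1.0
                break
    return w


@dataclass
class SmallWorldResult:
    """Small-world index with its null-model provenance."""

    sigma: float
    clustering: float
    path_length: float
    c_rand_mean: float
    c_rand_sd: float
    l_rand_mean: float
    l_rand_sd: float
    n_null: int
    swaps_per_edge: int
    seed: int | None


def small_worldness(g, n_null: int = 100, swaps_per_edge: int = 10,
                    seed: int | None = None,
                    rng: np.random.Generator | None = None) -> SmallWorldResult:
    """Small-world index sigma against degree-preserving rewired surrogates.

    ``sigma = (C/C_rand) / (L/L_rand)`` where C is the mean Onnela
    clustering coefficient, L the characteristic path length, and
    C_rand/L_rand are means over ``n_null`` Maslov-Sneppen rewired
    surrogates carrying the original weight multiset shuffled onto the
    rewired topology.  Deterministic given the seed.  sigma > 1
    indicates small-world organization.
    """
    if n_null < 1:
        raise ValueError("n_null must be >= 1")
    w = _as_matrix(g)
    if rng is None:
        rng = np.random.default_rng(seed)
    _, c_obs = clustering_weighted(w)
    l_obs = path_length(w)
    a = (w > 0).astype(int)
    iu, ju = np.triu_indices(w.shape[0], k=1)
    mask = a[iu, ju] > 0
    weight_pool = w[iu[mask], ju[mask]]
    c_null = np.empty(n_null)
    l_null = np.empty(n_null)
    for r in range(n_null):
        ar = _rewire_degree_preserving(a, swaps_per_edge, rng)
        wi, wj = np.triu_indices(w.shape[0], k=1)
        sel = ar[wi, wj] > 0
        shuffled = rng.permutation(weight_pool)
        wr = np.zeros_like(w)
        wr[wi[sel], wj[sel]] = shuffled
        wr = wr + wr.T
        _, c_null[r] = clustering_weighted(wr)
        l_null[r] = path_length(wr, warn_disconnected=False)
    c_rand = float(c_null.mean())
    l_rand = float(l_null.mean())
    if c_rand == 0 or l_obs == 0:
        raise ValueError("degenerate null model: cannot form sigma")
    sigma = (c_obs / c_rand) / (l_obs / l_rand)
    return SmallWorldResult(
        sigma=float(sigma), clustering=c_obs, path_length=l_obs,
        c_rand_mean=c_rand, c_rand_sd=float(c_null.std(ddof=0)),
        l_rand_mean=l_rand, l_rand_sd=float(l_null.std(ddof=0)),
        n_null=n_null, swaps_per_edge=swaps_per_edge, seed=seed,
    )


@dataclass
class NetworkMetricSet:
    """The weighted graph measures of one (sub)graph."""

    density: float
    clustering_mean: float
    transitivity: float
    path_length: float
    global_efficiency: float
    local_efficiency_mean: float
    assortativity: float
    sigma: float | None = None
    rich_club: dict[int, float] = field(default_factory=dict)
    small_world: SmallWorldResult | None = None

    def to_dict(self) -> dict[str, float]:
        out = {
            "density": self.density,
            "clustering_mean": self.clustering_mean,
            "transitivity": self.transitivity,
            "path_length": self.path_length,
            "global_efficiency": self.global_efficiency,
            "local_efficiency_mean": self.local_efficiency_mean,
            "assortativity": self.assortativity,
        }
        if self.sigma is not None:
            out["small_worldness"] = self.sigma
        return out


def compute_metrics(g, n_null: int | None = None, swaps_per_edge: int = 10,
                    seed: int | None = None,
                    rich_club_levels: bool = False) -> NetworkMetricSet:
    """Compute the full metric set for one graph view.

    Small-worldness is computed only when ``n_null`` is given (it is the
    one expensive, stochastic measure).  Rich-club coefficients at all
    degree levels are included when ``rich_club_levels`` is set.
    """
    w = _as_matrix(g)
    _, c_mean = clustering_weighted(w)
    _, le_mean = local_efficiency(w)
    sw = None
    sigma = None
    if n_null is not None:
        sw = small_worldness(w, n_null=n_null, swaps_per_edge=swaps_per_edge, seed=seed)
        sigma = sw.sigma
    return NetworkMetricSet(
        density=density(w),
        clustering_mean=c_mean,
        transitivity=transitivity_weighted(w),
        path_length=path_length(w),
        global_efficiency=global_efficiency(w),
        local_efficiency_mean=le_mean,
        assortativity=assortativity(w),
        sigma=sigma,
        rich_club=rich_club_curve(w) if rich_club_levels else {},
        small_world=sw,
    )
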