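"""Graph-theoretic network metrics over the sparsity grid.

Local (per-region) metrics: degree centrality, betweenness centrality
(Brandes, unnormalized, unordered source-target pairs), nodal clustering
coefficient, nodal efficiency, local efficiency, and nodal shortest path.
Global metrics: network (global) efficiency, average shortest path length,
and small-worldness sigma against degree-preserving rewired null networks.

Conventions for disconnected graphs follow the common connectomics toolbox
behavior: efficiency-type metrics treat unreachable pairs as contributing
1/inf = 0, while path-length averages exclude unreachable pairs and report
how many were excluded.  Per-metric values across the density grid are
aggregated by trapezoidal area under the metric-versus-k curve (AUC).

Shortest paths are delegated to :mod:`scipy.sparse.csgraph`, betweenness and
degree-preserving rewiring build on :mod:`networkx`; the remaining metrics
are vectorized numpy on the adjacency matrix.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import shortest_path as _csgraph_shortest_path

from .connectivity import BinaryNetwork, WeightedNetwork

__all__ = [
    "LOCAL_METRICS",
    "GLOBAL_METRICS",
    "NodalMetrics",
    "GlobalMetrics",
    "SmallWorldResult",
    "shortest_paths",
    "nodal_metrics",
    "global_metrics",
    "rewire_preserving_degree",
    "small_worldness",
    "auc_aggregate",
    "weighted_metrics",
]

LOCAL_METRICS = (
    "degree",
    "betweenness",
    "clustering",
    "nodal_efficiency",
    "local_efficiency",
    "nodal_shortest_path",
)
GLOBAL_METRICS = ("global_efficiency", "char_path_length", "small_worldness")


@dataclass
class NodalMetrics:
    """Per-region metric vectors at one sparsity level.

    ``nodal_shortest_path`` is NaN for isolated nodes (no reachable peers).
    """

    degree: np.ndarray
    betweenness: np.ndarray
    clustering: np.ndarray
    nodal_efficiency: np.ndarray
    local_efficiency: np.ndarray
    nodal_shortest_path: np.ndarray
    sparsity: float
    roi_labels: tuple[str, ...]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {m: getattr(self, m) for m in LOCAL_METRICS},
            index=pd.Index(self.roi_labels, name="region"),
        )


@dataclass
class GlobalMetrics:
    """Whole-network summary at one sparsity level.

    ``n_unreachable_pairs`` counts unordered node pairs excluded from the
    average shortest path length because no path connects them.
    """

    global_efficiency: float
    char_path_length: float
    n_unreachable_pairs: int
    sparsity: float


@dataclass
class SmallWorldResult:
    """Small-worldness sigma = gamma / lambda against rewired nulls.

    gamma = C / <C_null>, lambda = L / <L_null>; null averages are taken over
    ``n_nulls`` degree-preserving rewirings (mean-of-nulls convention).
    """

    sigma: float
    gamma: float
    lam: float
    clustering: float
    char_path_length: float
    clustering_null: float
    char_path_length_null: float
    n_nulls: int


def _adjacency(net: BinaryNetwork | WeightedNetwork) -> tuple[np.ndarray, bool]:
    if isinstance(net, BinaryNetwork):
        return net.adjacency.astype(float), False
    if isinstance(net, WeightedNetwork):
        return net.weights, True
    raise TypeError(f"expected BinaryNetwork or WeightedNetwork, got {type(net)!r}")


def _bfs_distances(a: np.ndarray) -> np.ndarray:
    """All-pairs hop-count distances by frontier expansion (vectorized BFS)."""
    n = a.shape[0]
    adj = (a > 0).astype(np.uint8)
    d = np.full((n, n), np.inf)
    np.fill_diagonal(d, 0.0)
    known = np.eye(n, dtype=bool)
    frontier = (adj > 0) & ~known
    dist = 1
    while frontier.any():
        d[frontier] = dist
        known |= frontier
        frontier = ((frontier.astype(np.uint8) @ adj) > 0) & ~known
        dist += 1
    return d


def shortest_paths(net: BinaryNetwork | WeightedNetwork) -> np.ndarray:
    """All-pairs shortest-path distance matrix (+inf where unreachable).

    Binary graphs use hop counts; weighted graphs use edge lengths 1/w so that
    strong couplings are short.
    """
    a, weighted = _adjacency(net)
    if weighted:
        with np.errstate(divide="ignore"):
            lengths = np.where(a > 0, 1.0 / np.where(a > 0, a, 1.0), 0.0)
        return _csgraph_shortest_path(csr_matrix(lengths), method="D", directed=False)
    return _bfs_distances(a)


def _efficiency_from_distances(d: np.ndarray) -> float:
    n = d.shape[0]
    if n < 2:
        return 0.0
    with np.errstate(divide="ignore"):
        inv = 1.0 / d
    np.fill_diagonal(inv, 0.0)
    inv[~np.isfinite(inv)] = 0.0
    return float(inv.sum() / (n * (n - 1)))


def _betweenness(a: np.ndarray, weighted: bool) -> np.ndarray:
    if weighted:
        g = nx.from_numpy_array(np.where(a > 0, 1.0 / np.where(a > 0, a, 1.0), 0.0))
        bc = nx.betweenness_centrality(g, normalized=False, weight="weight")
    else:
        g = nx.from_numpy_array(a)
        bc = nx.betweenness_centrality(g, normalized=False)
    return np.array([bc[i] for i in range(a.shape[0])])


def nodal_metrics(
    net: BinaryNetwork | WeightedNetwork,
    normalized_betweenness: bool = False,
) -> NodalMetrics:
    """The six per-region metrics of a binary network at one density.

    Clustering of nodes with fewer than two neighbors is 0, as is their local
    efficiency; the nodal shortest path of an isolated node is NaN.
    Betweenness is unnormalized by default (``normalized_betweenness`` divides
    by (N-1)(N-2)/2, a constant within a fixed parcellation).
    """
    a, weighted = _adjacency(net)
    if weighted:
        return _weighted_nodal_metrics(net, normalized_betweenness)
    n = a.shape[0]
    deg = a.sum(axis=1)

    # triangles through each node: diag(A^3) / 2
    tri = np.einsum("ij,jk,ki->i", a, a, a) / 2.0
    denom = deg * (deg - 1)
    clustering = np.where(denom > 0, 2.0 * tri / np.where(denom > 0, denom, 1), 0.0)

    d = shortest_paths(net)
    with np.errstate(divide="ignore"):
        inv = 1.0 / d
    np.fill_diagonal(inv, 0.0)
    inv[~np.isfinite(inv)] = 0.0
    nodal_eff = inv.sum(axis=1) / (n - 1)

    finite = np.isfinite(d) & ~np.eye(n, dtype=bool)
    n_reach = finite.sum(axis=1)
    with np.errstate(invalid="ignore"):
        nsp = np.where(
            n_reach > 0,
            np.where(finite, d, 0.0).sum(axis=1) / np.where(n_reach > 0, n_reach, 1),
            np.nan,
        )

    loc_eff = np.zeros(n)
    for i in range(n):
        nbr = np.flatnonzero(a[i] > 0)
        if nbr.size < 2:
            continue
        sub = a[np.ix_(nbr, nbr)]
        loc_eff[i] = _efficiency_from_distances(_bfs_distances(sub))

    bc = _betweenness(a, weighted=False)
    if normalized_betweenness and n > 2:
        bc = bc / ((n - 1) * (n - 2) / 2.0)

    return NodalMetrics(
        degree=deg.astype(float),
        betweenness=bc,
        clustering=clustering,
        nodal_efficiency=nodal_eff,
        local_efficiency=loc_eff,
        nodal_shortest_path=nsp,
        sparsity=net.sparsity,
        roi_labels=net.roi_labels,
    )


def global_metrics(net: BinaryNetwork | WeightedNetwork) -> GlobalMetrics:
    """Network efficiency and average shortest path length.

    Efficiency averages 1/d over all ordered pairs (1/inf = 0); the path
    length averages d over reachable ordered pairs only, reporting the number
    of excluded (unordered) pairs.  Raises if no pair is reachable.
    """
    d = shortest_paths(net)
    n = d.shape[0]
    off = ~np.eye(n, dtype=bool)
    finite = np.isfinite(d) & off
    if not finite.any():
        raise ValueError("network has no connected node pair")
    eff = _efficiency_from_distances(d)
    cpl = float(d[finite].mean())
    n_excluded = int((off & ~finite).sum()) // 2
    return GlobalMetrics(
        global_efficiency=eff,
        char_path_length=cpl,
        n_unreachable_pairs=n_excluded,
        sparsity=net.sparsity,
    )


def rewire_preserving_degree(
    net: BinaryNetwork,
    n_swaps: int | None = None,
    seed=None,
    max_tries: int | None = None,
) -> BinaryNetwork:
    """Maslov-Sneppen double-edge-swap randomization.

    Repeatedly picks two edges (a, b), (c, d) and rewires them to (a, d),
    (c, b) when neither self-loops nor multi-edges would arise, preserving
    every node's degree.  Attempts that would break simplicity are discarded;
    the procedure stops after ``n_swaps`` successful swaps (default 10x the
    edge count) or ``max_tries`` attempts, so graphs with no admissible swap
    (e.g. complete graphs) are returned unchanged.
    """
    rng = np.random.default_rng(seed)
    iu, ju = np.nonzero(np.triu(net.adjacency, k=1))
    edges = list(zip(iu.tolist(), ju.tolist()))
    n_edges = len(edges)
    if n_edges < 2:
        return BinaryNetwork(
            adjacency=net.adjacency.copy(),
            sparsity=net.sparsity,
            roi_labels=net.roi_labels,
        )
    if n_swaps is None:
        n_swaps = 10 * n_edges
    if max_tries is None:
        max_tries = 100 * n_swaps
    edge_set = set(edges)
    swaps = tries = 0
    chunk = 2048  # draw proposals in batches; per-call RNG overhead dominates otherwise
    while swaps < n_swaps and tries < max_tries:
        m = min(chunk, max_tries - tries)
        pairs = rng.integers(0, n_edges, size=(m, 2)).tolist()
        flips = (rng.random(m) < 0.5).tolist()
        for (e1, e2), flip in zip(pairs, flips):
            tries += 1
            if e1 == e2:
                continue
            a, b = edges[e1]
            c, d = edges[e2]
            if flip:
                c, d = d, c
            # candidate rewiring: (a, d), (c, b)
            if a == d or c == b:
                continue
            new1 = (a, d) if a < d else (d, a)
            new2 = (c, b) if c < b else (b, c)
            if new1 == new2 or new1 in edge_set or new2 in edge_set:
                continue
            edge_set.discard(edges[e1])
            edge_set.discard(edges[e2])
            edge_set.add(new1)
            edge_set.add(new2)
            edges[e1] = new1
            edges[e2] = new2
            swaps += 1
            if swaps >= n_swaps:
                break
    adj = np.zeros_like(net.adjacency)
    if edges:
        ii, jj = zip(*edges)
        adj[list(ii), list(jj)] = 1
        adj |= adj.T
    return BinaryNetwork(
        adjacency=adj, sparsity=net.sparsity, roi_labels=net.roi_labels
    )


def small_worldness(
    net: BinaryNetwork,
    n_nulls: int = 100,
    seed=None,
) -> SmallWorldResult:
    """Small-worldness sigma relative to degree-matched rewired networks.

    sigma = (C/C_null) / (L/L_null) with C the mean nodal clustering, L the
    average shortest path length, and null values averaged over ``n_nulls``
    independent rewirings (seeded, hence reproducible).  sigma is NaN when the
    null clustering mean is zero.
    """
    nm = nodal_metrics(net)
    gm = global_metrics(net)
    c_obs = float(nm.clustering.mean())
    l_obs = gm.char_path_length
    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    c_null = np.empty(n_nulls)
    l_null = np.empty(n_nulls)
    for idx, child in enumerate(ss.spawn(n_nulls)):
        null = rewire_preserving_degree(net, seed=child)
        a = null.adjacency.astype(float)
        deg = a.sum(axis=1)
        tri = np.einsum("ij,jk,ki->i", a, a, a) / 2.0
        denom = deg * (deg - 1)
        c_null[idx] = np.where(
            denom > 0, 2.0 * tri / np.where(denom > 0, denom, 1), 0.0
        ).mean()
        l_null[idx] = global_metrics(null).char_path_length
    c_bar = float(c_null.mean())
    l_bar = float(l_null.mean())
    if c_bar == 0 or l_bar == 0 or l_obs == 0:
        sigma = gamma = lam = np.nan
        if c_bar > 0:
            gamma = c_obs / c_bar
        if l_bar > 0:
            lam = l_obs / l_bar
    else:
        gamma = c_obs / c_bar
        lam = l_obs / l_bar
        sigma = gamma / lam
    return SmallWorldResult(
        sigma=float(sigma),
        gamma=float(gamma),
        lam=float(lam),
        clustering=c_obs,
        char_path_length=l_obs,
        clustering_null=c_bar,
        char_path_length_null=l_bar,
        n_nulls=n_nulls,
    )


def auc_aggregate(values_by_k) -> tuple[float, int]:
    """Trapezoidal area under the metric-versus-density curve.

    ``values_by_k`` maps density k to the metric value there (>= 2 strictly
    increasing grid points).  Returns ``(auc, n_missing)``: if any grid point
    is NaN the AUC itself is NaN and ``n_missing`` counts the gaps.
    """
    items = sorted((float(k), float(v)) for k, v in dict(values_by_k).items())
    if len(items) < 2:
        raise ValueError("AUC aggregation needs at least two grid points")
    ks = np.array([k for k, _ in items])
    ys = np.array([v for _, v in items])
    if np.any(np.diff(ks) <= 0):
        raise ValueError("threshold grid must be strictly increasing")
    n_missing = int(np.isnan(ys).sum())
    if n_missing:
        return float("nan"), n_missing
    return float(np.trapezoid(ys, ks)), 0


def _weighted_nodal_metrics(
    net: WeightedNetwork, normalized_betweenness: bool = False
) -> NodalMetrics:
    """Weighted analogues: strength for degree, Onnela clustering, 1/w lengths."""
    w = net.weights
    n = w.shape[0]
    strength = w.sum(axis=1)

    g = nx.from_numpy_array(w)
    cl = nx.clustering(g, weight="weight")  # Onnela geometric-mean form
    clustering = np.array([cl[i] for i in range(n)])

    d = shortest_paths(net)
    with np.errstate(divide="ignore"):
        inv = 1.0 / d
    np.fill_diagonal(inv, 0.0)
    inv[~np.isfinite(inv)] = 0.0
    nodal_eff = inv.sum(axis=1) / (n - 1)

    off = ~np.eye(n, dtype=bool)
    finite = np.isfinite(d) & off
    n_reach = finite.sum(axis=1)
    nsp = np.where(
        n_reach > 0,
        np.where(finite, d, 0.0).sum(axis=1) / np.where(n_reach > 0, n_reach, 1),
        np.nan,
    )

    loc_eff = np.zeros(n)
    for i in range(n):
        nbr = np.flatnonzero(w[i] > 0)
        if nbr.size < 2:
            continue
        sub = w[np.ix_(nbr, nbr)]
        with np.errstate(divide="ignore"):
            lengths = np.where(sub > 0, 1.0 / np.where(sub > 0, sub, 1.0), 0.0)
        dsub = _csgraph_shortest_path(csr_matrix(lengths), method="D", directed=False)
        loc_eff[i] = _efficiency_from_distances(dsub)

    bc = _betweenness(w, weighted=True)
    if normalized_betweenness and n > 2:
        bc = bc / ((n - 1) * (n - 2) / 2.0)

    return NodalMetrics(
        degree=strength,
        betweenness=bc,
        clustering=clustering,
        nodal_efficiency=nodal_eff,
        local_efficiency=loc_eff,
        nodal_shortest_path=nsp,
        sparsity=net.sparsity,
        roi_labels=net.roi_labels,
    )


def weighted_metrics(net: WeightedNetwork) -> tuple[NodalMetrics, GlobalMetrics]:
    """Nodal and global metrics of a weighted (un-binarized) network."""
    return _weighted_nodal_metrics(net), global_metrics(net)
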