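"""Functional-connectivity matrices and proportional sparsity thresholding.

A subject-session recording is a T x N matrix of regional signals (T frames,
N regions of interest).  Edges of the functional network are Pearson
correlations between regional timeseries; the full correlation matrix is then
sparsified by keeping the top k-percentile of unique off-diagonal values as
edges, for k on a grid of densities (default 0.05 ... 0.50), yielding one
simple undirected graph per density.  A weighted (un-binarized) variant keeps
the correlation values themselves as edge weights.

Ranking is by signed correlation by default (strong positive couplings are
kept first); pass ``absolute=True`` to rank by magnitude instead.  Ties at
the cutoff are broken by ascending (i, j) index so that thresholded networks
are nested across the grid and fully reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "DEFAULT_K_GRID",
    "RoiTimeseries",
    "ConnectivityMatrix",
    "BinaryNetwork",
    "WeightedNetwork",
    "pearson_fc",
    "binarize_top_k",
    "threshold_series",
    "weighted_network",
]

#: Default sparsity grid: 5% to 50% of possible edges in steps of 5%.
DEFAULT_K_GRID: tuple[float, ...] = tuple(round(0.05 * i, 2) for i in range(1, 11))

SESSIONS = ("baseline", "followup")


def _as_labels(labels, n: int) -> tuple[str, ...]:
    if labels is None:
        labels = [f"R{i:03d}" for i in range(n)]
    labels = tuple(str(x) for x in labels)
    if len(labels) != n:
        raise ValueError(f"expected {n} ROI labels, got {len(labels)}")
    if len(set(labels)) != len(labels):
        raise ValueError("ROI labels must be unique")
    return labels


@dataclass
class RoiTimeseries:
    """One subject-session recording: T frames x N regions."""

    values: np.ndarray
    roi_labels: tuple[str, ...] | None = None
    subject_id: str = ""
    session: str = "baseline"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("timeseries must be a 2-D (frames x regions) array")
        t, n = self.values.shape
        if t < 3:
            raise ValueError(f"need at least 3 frames, got {t}")
        if not np.all(np.isfinite(self.values)):
            bad = np.argwhere(~np.isfinite(self.values))[0]
            raise ValueError(
                f"non-finite value at frame {bad[0]}, region column {bad[1]}"
            )
        self.roi_labels = _as_labels(self.roi_labels, n)

    @property
    def n_frames(self) -> int:
        return self.values.shape[0]

    @property
    def n_regions(self) -> int:
        return self.values.shape[1]


@dataclass
class ConnectivityMatrix:
    """N x N Pearson correlation matrix with unit diagonal."""

    r: np.ndarray
    roi_labels: tuple[str, ...] | None = None

    def __post_init__(self) -> None:
        self.r = np.asarray(self.r, dtype=float)
        n = self.r.shape[0]
        if self.r.shape != (n, n):
            raise ValueError("correlation matrix must be square")
        if not np.allclose(self.r, self.r.T, atol=1e-10):
            raise ValueError("correlation matrix must be symmetric")
        if not np.allclose(np.diag(self.r), 1.0, atol=1e-10):
            raise ValueError("correlation matrix must have unit diagonal")
        if np.any(np.abs(self.r) > 1 + 1e-10):
            raise ValueError("correlations must lie in [-1, 1]")
        self.roi_labels = _as_labels(self.roi_labels, n)

    @property
    def n_regions(self) -> int:
        return self.r.shape[0]


@dataclass
class BinaryNetwork:
    """Simple undirected graph from top-k thresholding at density ``sparsity``."""

    adjacency: np.ndarray
    sparsity: float
    roi_labels: tuple[str, ...] | None = None

    def __post_init__(self) -> None:
        a = np.asarray(self.adjacency)
        n = a.shape[0]
        if a.shape != (n, n):
            raise ValueError("adjacency must be square")
        if not np.array_equal(a, a.T):
            raise ValueError("adjacency must be symmetric")
        if np.any(np.diag(a) != 0):
            raise ValueError("adjacency must have zero diagonal")
        if not np.isin(a, (0, 1)).all():
            raise ValueError("adjacency entries must be 0/1")
        self.adjacency = a.astype(np.int8)
        self.roi_labels = _as_labels(self.roi_labels, n)

    @property
    def n_regions(self) -> int:
        return self.adjacency.shape[0]

    @property
    def n_edges(self) -> int:
        return int(self.adjacency.sum()) // 2


@dataclass
class WeightedNetwork:
    """Nonnegative weighted graph (retained correlations as weights).

    ``n_negative_zeroed`` counts retained edges whose correlation was negative
    and was therefore set to zero.
    """

    weights: np.ndarray
    sparsity: float
    roi_labels: tuple[str, ...] | None = None
    n_negative_zeroed: int = 0

    def __post_init__(self) -> None:
        w = np.asarray(self.weights, dtype=float)
        n = w.shape[0]
        if w.shape != (n, n):
            raise ValueError("weight matrix must be square")
        if not np.allclose(w, w.T, atol=1e-12):
            raise ValueError("weight matrix must be symmetric")
        if np.any(np.diag(w) != 0):
            raise ValueError("weight matrix must have zero diagonal")
        if np.any(w < 0):
            raise ValueError("weights must be nonnegative")
        self.weights = w
        self.roi_labels = _as_labels(self.roi_labels, n)

    @property
    def n_regions(self) -> int:
        return self.weights.shape[0]


def pearson_fc(ts: RoiTimeseries) -> ConnectivityMatrix:
    """Pearson correlation matrix of the regional timeseries.

    Raises ``ValueError`` naming the ROI if any region has zero variance.
    """
    x = ts.values
    sd = x.std(axis=0)
    zero = np.flatnonzero(sd == 0)
    if zero.size:
        raise ValueError(
            f"zero-variance timeseries for ROI {ts.roi_labels[zero[0]]!r}"
        )
    r = np.corrcoef(x, rowvar=False)
    r = np.clip((r + r.T) / 2.0, -1.0, 1.0)
    np.fill_diagonal(r, 1.0)
    return ConnectivityMatrix(r=r, roi_labels=ts.roi_labels)


def _ranked_pairs(fc: ConnectivityMatrix, absolute: bool):
    """Unique off-diagonal entries ordered by descending value, ties by (i, j)."""
    iu, ju = np.triu_indices(fc.n_regions, k=1)
    vals = fc.r[iu, ju]
    key = np.abs(vals) if absolute else vals
    # np.lexsort: last key is primary; -key descending, then i, then j ascending
    order = np.lexsort((ju, iu, -key))
    return iu, ju, vals, order


def _edge_count(k: float, n_pairs: int) -> int:
    if not 0 < k <= 1:
        raise ValueError(f"sparsity k must be in (0, 1], got {k}")
    e = int(np.floor(k * n_pairs + 0.5))  # round-half-up
    if e == 0:
        raise ValueError(f"sparsity k={k} keeps zero edges (degenerate network)")
    return e


def binarize_top_k(fc: ConnectivityMatrix, k: float, absolute: bool = False) -> BinaryNetwork:
    """Keep the top round(k * N(N-1)/2) correlations as unweighted edges."""
    iu, ju, vals, order = _ranked_pairs(fc, absolute)
    e = _edge_count(k, vals.size)
    sel = order[:e]
    a = np.zeros_like(fc.r, dtype=np.int8)
    a[iu[sel], ju[sel]] = 1
    a |= a.T
    return BinaryNetwork(adjacency=a, sparsity=float(k), roi_labels=fc.roi_labels)


def threshold_series(
    fc: ConnectivityMatrix,
    k_grid=DEFAULT_K_GRID,
    absolute: bool = False,
) -> list[BinaryNetwork]:
    """Binarize over a strictly increasing density grid.

    The deterministic tie-break makes the edge sets nested: the network at a
    smaller k is a subgraph of the network at any larger k.
    """
    k_grid = [float(k) for k in k_grid]
    if len(k_grid) == 0:
        raise ValueError("empty threshold grid")
    if any(b <= a for a, b in zip(k_grid, k_grid[1:])):
        raise ValueError("threshold grid must be strictly increasing")
    return [binarize_top_k(fc, k, absolute=absolute) for k in k_grid]


def weighted_network(
    fc: ConnectivityMatrix,
    k: float | None = None,
    absolute: bool = False,
) -> WeightedNetwork:
    """Weighted network with retained correlations as edge weights.

    With ``k`` given, the support is the same top-k edge set as
    :func:`binarize_top_k`; un-thresholded (``k=None``) every positive
    off-diagonal entry is kept.  Retained negative correlations are zeroed and
    counted in ``n_negative_zeroed``.
    """
    iu, ju, vals, order = _ranked_pairs(fc, absolute)
    if k is None:
        sel = np.arange(vals.size)
        sparsity = 1.0
    else:
        sel = order[: _edge_count(k, vals.size)]
        sparsity = float(k)
    w = np.zeros_like(fc.r)
    w[iu[sel], ju[sel]] = vals[sel]
    n_neg = int((w < 0).sum())
    w[w < 0] = 0.0
    w = w + w.T
    if not w.any():
        raise ValueError("all retained weights are zero")
    return WeightedNetwork(
        weights=w,
        sparsity=sparsity,
        roi_labels=fc.roi_labels,
        n_negative_zeroed=n_neg,
    )
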