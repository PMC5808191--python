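"""Thresholded brain networks and their node-wise graph metrics.

A subject's regional time series become a functional-connectivity matrix
of absolute Pearson correlations; thresholding that matrix yields a
binary brain graph from which four metric families are computed:
degree, pairwise shortest-path length (hop count), local efficiency and
clustering coefficient.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np
from scipy.sparse.csgraph import shortest_path as _csgraph_shortest_path

from .regions import default_region_ids

DEFAULT_THRESHOLD = 0.25


def _check_square_symmetric(values: np.ndarray, what: str) -> None:
    if values.ndim != 2 or values.shape[0] != values.shape[1]:
        raise ValueError(f"{what} must be a square matrix, got shape {values.shape}")
    if not np.allclose(values, values.T):
        raise ValueError(f"{what} must be symmetric")


@dataclass
class ROITimeSeries:
    """T x N matrix of regional mean signals for one subject.

    Rows are time points, columns are regions.  At least three time
    points are required (a Pearson correlation from fewer is degenerate)
    and no region may have a constant signal.
    """

    values: np.ndarray
    region_ids: list[str] = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("time series must be a 2-D (T x N) array")
        if self.n_timepoints < 3:
            raise ValueError(
                f"need at least 3 time points, got {self.n_timepoints}"
            )
        if self.region_ids is None:
            self.region_ids = default_region_ids(self.n_regions)
        if len(self.region_ids) != self.n_regions:
            raise ValueError("region_ids length does not match column count")
        sd = self.values.std(axis=0)
        if np.any(sd == 0):
            bad = [self.region_ids[i] for i in np.flatnonzero(sd == 0)]
            raise ValueError(f"constant (zero-variance) signal in region(s): {bad}")

    @property
    def n_timepoints(self) -> int:
        return self.values.shape[0]

    @property
    def n_regions(self) -> int:
        return self.values.shape[1]


@dataclass
class ConnectivityMatrix:
    """N x N absolute Pearson correlations; symmetric, zero diagonal."""

    values: np.ndarray
    region_ids: list[str] = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        _check_square_symmetric(self.values, "connectivity")
        if np.any(self.values < 0) or np.any(self.values > 1):
            raise ValueError("connectivity entries must lie in [0, 1]")
        np.fill_diagonal(self.values, 0.0)
        if self.region_ids is None:
            self.region_ids = default_region_ids(self.n_regions)
        if len(self.region_ids) != self.n_regions:
            raise ValueError("region_ids length does not match matrix size")

    @property
    def n_regions(self) -> int:
        return self.values.shape[0]


@dataclass
class BrainGraph:
    """Binary adjacency obtained by thresholding a connectivity matrix."""

    adjacency: np.ndarray
    threshold: float = DEFAULT_THRESHOLD
    region_ids: list[str] = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.adjacency = np.asarray(self.adjacency)
        _check_square_symmetric(self.adjacency, "adjacency")
        if not np.isin(self.adjacency, (0, 1)).all():
            raise ValueError("adjacency must be binary")
        self.adjacency = self.adjacency.astype(np.int8)
        np.fill_diagonal(self.adjacency, 0)
        if self.region_ids is None:
            self.region_ids = default_region_ids(self.n_regions)
        if len(self.region_ids) != self.n_regions:
            raise ValueError("region_ids length does not match matrix size")

    @property
    def n_regions(self) -> int:
        return self.adjacency.shape[0]

    def to_networkx(self) -> nx.Graph:
        return nx.from_numpy_array(self.adjacency)


@dataclass
class GraphMetrics:
    """The four node-wise metric families of one brain graph.

    ``shortest_path`` stores hop counts with disconnected pairs encoded
    by the finite sentinel N (one more than any achievable path length),
    so that downstream feature vectors never contain infinities.
    """

    degree: np.ndarray
    shortest_path: np.ndarray
    local_efficiency: np.ndarray
    clustering: np.ndarray


def pearson_connectivity(ts: ROITimeSeries) -> ConnectivityMatrix:
    """Absolute Pearson correlation between every pair of regional signals."""
    r = np.corrcoef(ts.values, rowvar=False)
    conn = np.abs(r)
    # |r| can exceed 1 by floating error only
    np.clip(conn, 0.0, 1.0, out=conn)
    conn = (conn + conn.T) / 2.0
    np.fill_diagonal(conn, 0.0)
    return ConnectivityMatrix(conn, list(ts.region_ids))


def threshold_graph(
    conn: ConnectivityMatrix, tau: float = DEFAULT_THRESHOLD
) -> BrainGraph:
    """Binarize connectivity: edge iff |r| strictly exceeds ``tau``.

    The strict rule means an entry exactly equal to the threshold does
    not become an edge.
    """
    if not 0.0 <= tau < 1.0:
        raise ValueError(f"threshold must lie in [0, 1), got {tau}")
    adj = (conn.values > tau).astype(np.int8)
    np.fill_diagonal(adj, 0)
    return BrainGraph(adj, threshold=tau, region_ids=list(conn.region_ids))


def degrees(g: BrainGraph) -> np.ndarray:
    """Node degrees k_i (row sums of the adjacency matrix)."""
    return g.adjacency.sum(axis=1).astype(np.int64)


def shortest_paths(g: BrainGraph, sentinel: int | None = None) -> np.ndarray:
    """All-pairs unweighted shortest-path lengths (hop counts).

    Disconnected pairs receive the finite ``sentinel`` (default: N, the
    number of nodes — strictly larger than any realizable path length
    N-1).
    """
    n = g.n_regions
    if sentinel is None:
        sentinel = n
    d = _csgraph_shortest_path(g.adjacency, method="D", unweighted=True)
    d[np.isinf(d)] = sentinel
    return d.astype(np.int64)


def clustering_coefficients(g: BrainGraph) -> np.ndarray:
    """C_i = 2 t_i / (k_i (k_i - 1)); zero for nodes of degree < 2."""
    cc = nx.clustering(g.to_networkx())
    return np.array([cc[i] for i in range(g.n_regions)], dtype=float)


def local_efficiencies(g: BrainGraph) -> np.ndarray:
    """Latora-Marchiori nodal efficiency of each neighbourhood subgraph.

    E_loc,i averages 1/d_jh over ordered neighbour pairs (j, h) of node
    i, with d computed on the subgraph induced by the neighbours of i
    (node i itself excluded).  Unreachable neighbour pairs contribute 0;
    nodes of degree < 2 score 0.
    """
    adj = g.adjacency
    n = g.n_regions
    eff = np.zeros(n)
    for i in range(n):
        nbrs = np.flatnonzero(adj[i])
        k = nbrs.size
        if k < 2:
            continue
        sub = adj[np.ix_(nbrs, nbrs)]
        d = _csgraph_shortest_path(sub, method="D", unweighted=True)
        with np.errstate(divide="ignore"):
            inv = 1.0 / d
        inv[~np.isfinite(inv)] = 0.0  # diagonal and unreachable pairs
        eff[i] = inv.sum() / (k * (k - 1))
    return eff


def compute_metrics(g: BrainGraph, sentinel: int | None = None) -> GraphMetrics:
    """All four metric families of one brain graph."""
    return GraphMetrics(
        degree=degrees(g),
        shortest_path=shortest_paths(g, sentinel=sentinel),
        local_efficiency=local_efficiencies(g),
        clustering=clustering_coefficients(g),
    )
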