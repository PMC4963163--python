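"""Node- and network-level metrics for binary and weighted connectomes.

Binary metrics (degree, hop-count geodesics, triangle clustering) operate
on the 0/1 adjacency; weighted metrics (strength, max-weight geodesics,
Onnela and Zhang clustering) use the weighted adjacency.  The weighted
geodesic follows the "low-cost path" convention for brain networks: among
all paths with the minimum number of hops between two nodes, the geodesic
is the one with the *highest* sum of edge weights — a large d^w means a
strong, short route, not a long one.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy.sparse.csgraph import shortest_path

from .core import BinaryGraph, Connectome, binarize


@dataclass
class PathMatrix:
    """All-pairs geodesic lengths.

    ``mode`` is ``binary`` (entries are hop counts) or ``weighted``
    (entries are max weight sums along min-hop paths).  Unreachable pairs
    are NaN; the diagonal is 0.
    """

    mode: str
    values: np.ndarray
    node_labels: list[str]

    @property
    def n_nodes(self) -> int:
        return len(self.node_labels)

    def is_connected(self) -> bool:
        return not np.any(np.isnan(self.values))


@dataclass
class NodeMetricVector:
    """Per-node values of one metric, aligned with ``node_labels``."""

    name: str
    values: np.ndarray
    node_labels: list[str]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if len(self.values) != len(self.node_labels):
            raise ValueError("metric vector length does not match node labels")

    def as_series(self) -> pd.Series:
        return pd.Series(self.values, index=self.node_labels, name=self.name)

    def __getitem__(self, label: str) -> float:
        return float(self.values[self.node_labels.index(label)])


# -- node connectivity ---------------------------------------------------


def node_degree(g: BinaryGraph) -> NodeMetricVector:
    """Number of neighbors of each node: k_i = sum_j a_ij."""
    return NodeMetricVector("degree", g.adjacency.sum(axis=1), list(g.node_labels))


def node_strength(c: Connectome) -> NodeMetricVector:
    """Sum of incident edge weights of each node: s_i = sum_j w(e_ij)."""
    return NodeMetricVector("strength", c.weights.sum(axis=1), list(c.node_labels))


def cumulative_distribution(v: NodeMetricVector) -> pd.DataFrame:
    """Complementary cumulative distribution of a node metric.

    Rows are the distinct values in increasing order; ``fraction`` is the
    share of nodes with metric >= value, so the first row has fraction 1
    and fractions are non-increasing.
    """
    if len(v.values) == 0:
        raise ValueError("empty metric vector")
    vals = np.sort(np.unique(v.values))
    frac = [(v.values >= x).mean() for x in vals]
    return pd.DataFrame({"value": vals, "fraction": frac})


# -- geodesic paths ------------------------------------------------------


def binary_geodesics(g: BinaryGraph) -> PathMatrix:
    """Hop-count distances between all node pairs (breadth-first search)."""
    d = shortest_path(sp.csr_matrix(g.adjacency), method="D", unweighted=True,
                      directed=False)
    d[np.isinf(d)] = np.nan
    return PathMatrix("binary", d, list(g.node_labels))


def weighted_geodesics(c: Connectome) -> PathMatrix:
    """Max-weight-sum lengths along minimum-hop paths, for all pairs.

    For each reachable pair (i, j) with hop distance h, d^w_ij is the
    largest total edge weight over all i-j paths of exactly h edges.  The
    computation sweeps hop layers outward from each source: the best
    weight to a node at layer h is the max over its layer-(h-1) neighbors
    of their best weight plus the connecting edge.  A walk of exactly h
    edges ending at hop distance h cannot revisit a node (a revisit would
    waste at least two edges), so the layered recursion is exact.
    """
    w = c.weights
    n = c.n_nodes
    hops = shortest_path(sp.csr_matrix(w > 0), method="D", unweighted=True,
                         directed=False)
    out = np.full((n, n), np.nan)
    for s in range(n):
        h = hops[s]
        finite = np.isfinite(h)
        best = np.full(n, -np.inf)
        best[s] = 0.0
        max_h = int(h[finite].max()) if finite.any() else 0
        for level in range(1, max_h + 1):
            prev = np.flatnonzero(h == level - 1)
            cur = np.flatnonzero(h == level)
            sub = w[np.ix_(prev, cur)]
            cand = np.where(sub > 0, best[prev][:, None] + sub, -np.inf)
            best[cur] = cand.max(axis=0)
        out[s, finite] = best[finite]
        out[s, s] = 0.0
    return PathMatrix("weighted", out, list(c.node_labels))


def mean_geodesic(p: PathMatrix, node: str | None = None) -> float | NodeMetricVector:
    """Mean geodesic length from a node to the other N-1 nodes.

    With ``node=None`` returns the full per-node vector.  Raises on a
    disconnected graph: averaging only the finite entries would silently
    bias comparisons (restrict to the largest component first if that is
    the intended policy).
    """
    n = p.n_nodes
    if n < 2:
        raise ValueError("mean geodesic path requires at least 2 nodes")
    vals = p.values.copy()
    np.fill_diagonal(vals, np.nan)
    off_diag = ~np.eye(n, dtype=bool)
    if np.any(np.isnan(vals[off_diag])):
        raise ValueError(
            "graph is disconnected: some pairs are unreachable; restrict to "
            "the largest connected component to compute path metrics"
        )
    means = np.nansum(vals, axis=1) / (n - 1)
    vec = NodeMetricVector(f"mean_geodesic_{p.mode}", means, list(p.node_labels))
    return vec if node is None else vec[node]


# -- clustering ----------------------------------------------------------


def scale_weights(c: Connectome) -> np.ndarray:
    """Weights scaled by the network-wide maximum: w_hat in [0, 1], max 1.

    The maximum is taken over the network as currently thresholded.
    """
    mx = c.weights.max()
    if mx <= 0:
        raise ValueError("cannot scale weights of an edgeless network")
    return c.weights / mx


def _triangle_terms(m: np.ndarray) -> np.ndarray:
    # diag(M^3)[i] = sum over ordered neighbor pairs (j, m) of M_ij M_jm M_mi
    return np.einsum("ij,jk,ki->i", m, m, m)


def clustering_binary(g: BinaryGraph, node: str | None = None) -> float | NodeMetricVector:
    """Fraction of a node's neighbor pairs that are themselves connected.

    c_i = 2 E_i / (k_i (k_i - 1)) with E_i the number of edges among the
    neighbors of i; 0 by convention when k_i <= 1.
    """
    a = g.adjacency.astype(float)
    k = a.sum(axis=1)
    denom = k * (k - 1)
    with np.errstate(invalid="ignore", divide="ignore"):
        c = np.where(denom > 0, _triangle_terms(a) / denom, 0.0)
    vec = NodeMetricVector("clustering_binary", c, list(g.node_labels))
    return vec if node is None else vec[node]


def clustering_onnela(c: Connectome, node: str | None = None) -> float | NodeMetricVector:
    """Onnela weighted clustering: geometric-mean triangle intensities.

    c_i = (1 / (k_i (k_i - 1))) * sum_{j,m} (w_hat_ij w_hat_jm w_hat_mi)^(1/3)
    with w_hat the max-scaled weights and k_i the binary degree; 0 when
    k_i <= 1.  Equals the binary coefficient when all weights are equal.
    """
    w_hat = scale_weights(c)
    cbrt = np.cbrt(w_hat)
    k = (c.weights > 0).sum(axis=1).astype(float)
    denom = k * (k - 1)
    with np.errstate(invalid="ignore", divide="ignore"):
        vals = np.where(denom > 0, _triangle_terms(cbrt) / denom, 0.0)
    vec = NodeMetricVector("clustering_onnela", vals, list(c.node_labels))
    return vec if node is None else vec[node]


def clustering_zhang(c: Connectome, node: str | None = None) -> float | NodeMetricVector:
    """Zhang-Horvath weighted clustering: fully weight-based normalization.

    c_i = sum_{j,m} w_hat_ij w_hat_jm w_hat_mi
          / ((sum_j w_hat_ij)^2 - sum_j w_hat_ij^2),
    0 when the denominator vanishes (degree <= 1).  Unlike Onnela's
    variant it involves no binary degree, which makes it markedly more
    stable under count thresholding.
    """
    w_hat = scale_weights(c)
    s = w_hat.sum(axis=1)
    sq = (w_hat**2).sum(axis=1)
    denom = s**2 - sq
    with np.errstate(invalid="ignore", divide="ignore"):
        vals = np.where(denom > 0, _triangle_terms(w_hat) / denom, 0.0)
    vec = NodeMetricVector("clustering_zhang", vals, list(c.node_labels))
    return vec if node is None else vec[node]


CLUSTERING_MODES = ("binary", "onnela", "zhang")


def clustering(c: Connectome, mode: str, node: str | None = None):
    """Dispatch to one of the three clustering coefficients by mode name."""
    if mode == "binary":
        return clustering_binary(binarize(c), node)
    if mode == "onnela":
        return clustering_onnela(c, node)
    if mode == "zhang":
        return clustering_zhang(c, node)
    raise ValueError(f"unknown clustering mode {mode!r}; expected {CLUSTERING_MODES}")


def geodesics(c: Connectome, mode: str) -> PathMatrix:
    """Path matrix for a mode: hop counts for ``binary``, else weighted."""
    if mode == "binary":
        return binary_geodesics(binarize(c))
    if mode in ("weighted", "onnela", "zhang"):
        return weighted_geodesics(c)
    raise ValueError(f"unknown path mode {mode!r}")
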