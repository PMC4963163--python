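"""Core data model for dense weighted undirected connectomes.

A connectome is an undirected network whose nodes are gray-matter parcels
and whose edges are white-matter connections estimated from tractography.
Each edge carries two attributes: a dimensionless weight quantifying
connection strength, and the number of tractography streamlines supporting
it.  The streamline count is the thresholding variable; the weight is the
analysis variable.  Keeping both on the same object is what lets count
thresholds be applied identically to the binary and the weighted view of
the same network.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp
from scipy.sparse.csgraph import connected_components

logger = logging.getLogger("wconn")

#: Relative tolerance under which an asymmetric numeric input is treated as
#: round-off and symmetrized by averaging; larger asymmetries are an error.
SYMMETRY_RTOL = 1e-12


class ConnectomeError(ValueError):
    """Invalid connectome data (asymmetry, negative weights, bad shapes...)."""


@dataclass
class Connectome:
    """Undirected weighted network with optional per-edge streamline counts.

    Parameters
    ----------
    node_labels:
        N unique node names.  All file formats refer to nodes by label;
        positional indices are an internal detail.
    weights:
        N x N symmetric matrix of non-negative edge weights, zero diagonal.
        A zero entry means "no edge" (edge presence is strictly weight > 0).
    counts:
        Optional N x N symmetric matrix of non-negative integer streamline
        counts.  When present, counts > 0 exactly where weights > 0.
    metadata:
        Free-form provenance record (source file, applied threshold, seed...).
    """

    node_labels: list[str]
    weights: np.ndarray
    counts: np.ndarray | None = None
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.node_labels = [str(x) for x in self.node_labels]
        self.weights = np.asarray(self.weights, dtype=float)
        if self.counts is not None:
            self.counts = np.asarray(self.counts)

    # -- basic properties -------------------------------------------------

    @property
    def n_nodes(self) -> int:
        return len(self.node_labels)

    @property
    def has_counts(self) -> bool:
        return self.counts is not None

    @property
    def n_edges(self) -> int:
        """Number of undirected edges (weight > 0)."""
        iu = np.triu_indices(self.n_nodes, k=1)
        return int(np.count_nonzero(self.weights[iu]))

    def edge_pairs(self) -> list[tuple[int, int]]:
        """Index pairs (i < j) of present edges, in row-major order."""
        iu, ju = np.triu_indices(self.n_nodes, k=1)
        present = self.weights[iu, ju] > 0
        return list(zip(iu[present].tolist(), ju[present].tolist()))

    def edge_weight_list(self) -> np.ndarray:
        """Weights of present edges, aligned with :meth:`edge_pairs`."""
        iu, ju = np.triu_indices(self.n_nodes, k=1)
        w = self.weights[iu, ju]
        return w[w > 0]

    def index_of(self, label: str) -> int:
        try:
            return self.node_labels.index(label)
        except ValueError:
            raise KeyError(f"unknown node label {label!r}") from None

    def copy(self) -> "Connectome":
        return Connectome(
            node_labels=list(self.node_labels),
            weights=self.weights.copy(),
            counts=None if self.counts is None else self.counts.copy(),
            metadata=dict(self.metadata),
        )


@dataclass
class BinaryGraph:
    """0/1 symmetric adjacency with zero diagonal, derived from a Connectome."""

    node_labels: list[str]
    adjacency: np.ndarray

    def __post_init__(self) -> None:
        self.node_labels = [str(x) for x in self.node_labels]
        self.adjacency = np.asarray(self.adjacency)
        if self.adjacency.dtype.kind not in "iub":
            if not np.array_equal(self.adjacency, self.adjacency.astype(int)):
                raise ConnectomeError("binary adjacency must contain only 0/1")
        self.adjacency = self.adjacency.astype(np.int8)
        if np.any((self.adjacency != 0) & (self.adjacency != 1)):
            raise ConnectomeError("binary adjacency must contain only 0/1")

    @property
    def n_nodes(self) -> int:
        return len(self.node_labels)

    @property
    def n_edges(self) -> int:
        iu = np.triu_indices(self.n_nodes, k=1)
        return int(np.count_nonzero(self.adjacency[iu]))

    def index_of(self, label: str) -> int:
        try:
            return self.node_labels.index(label)
        except ValueError:
            raise KeyError(f"unknown node label {label!r}") from None


# -- validation ----------------------------------------------------------


def validate(c: Connectome) -> list[str]:
    """Check every connectome invariant; return human-readable violations.

    An empty list means the object is valid.  Each message names the
    violated invariant and the offending indices (first few occurrences).
    """
    out: list[str] = []
    n = c.n_nodes
    labels = c.node_labels
    if len(set(labels)) != n:
        out.append("node labels are not unique")
    w = c.weights
    if w.shape != (n, n):
        out.append(f"weights shape {w.shape} does not match {n} labels")
        return out
    asym = np.argwhere(w != w.T)
    if asym.size:
        i, j = asym[0]
        out.append(
            f"weights not symmetric at ({labels[i]},{labels[j]}): "
            f"{w[i, j]!r} vs {w[j, i]!r} ({len(asym)} entries)"
        )
    diag = np.flatnonzero(np.diag(w))
    if diag.size:
        out.append(f"nonzero weight diagonal at node(s) {[labels[i] for i in diag[:5]]}")
    neg = np.argwhere(w < 0)
    if neg.size:
        i, j = neg[0]
        out.append(f"negative weight at ({labels[i]},{labels[j]}): {w[i, j]}")
    if c.counts is not None:
        k = c.counts
        if k.shape != (n, n):
            out.append(f"counts shape {k.shape} does not match {n} labels")
            return out
        if not np.array_equal(k, np.round(np.asarray(k, dtype=float))):
            out.append("counts matrix contains non-integer entries")
        casym = np.argwhere(k != k.T)
        if casym.size:
            i, j = casym[0]
            out.append(
                f"counts not symmetric at ({labels[i]},{labels[j]}): "
                f"{k[i, j]!r} vs {k[j, i]!r}"
            )
        if np.flatnonzero(np.diag(k)).size:
            out.append("nonzero count diagonal")
        if np.any(np.asarray(k, dtype=float) < 0):
            out.append("negative streamline count")
        mism = np.argwhere((w > 0) != (np.asarray(k, dtype=float) > 0))
        if mism.size:
            i, j = mism[0]
            out.append(
                "edge-presence inconsistency (weight>0 xor count>0) at "
                f"({labels[i]},{labels[j]}): w={w[i, j]}, count={k[i, j]} "
                f"({len(mism)} entries)"
            )
    return out


def require_valid(c: Connectome) -> Connectome:
    """Raise :class:`ConnectomeError` listing all violations, if any."""
    problems = validate(c)
    if problems:
        raise ConnectomeError("; ".join(problems))
    return c


# -- derivations ---------------------------------------------------------


def binarize(c: Connectome) -> BinaryGraph:
    """Binary adjacency: 1 wherever the edge weight is strictly positive."""
    return BinaryGraph(node_labels=list(c.node_labels),
                       adjacency=(c.weights > 0).astype(np.int8))


def apply_count_threshold(c: Connectome, T: int) -> Connectome:
    """Remove edges supported by fewer than ``T`` streamlines.

    Thresholding acts on the streamline count, never on the weight: the
    same cut applies to the binary and the weighted view of the network.
    Edges with count >= T survive (inclusive); T = 0 is the identity.
    The input is left untouched; the result records the threshold in its
    metadata.
    """
    if T < 0 or int(T) != T:
        raise ValueError(f"threshold must be a non-negative integer, got {T!r}")
    if c.counts is None:
        raise ConnectomeError(
            "count thresholding requires a streamline-count matrix; "
            "this connectome carries weights only"
        )
    out = c.copy()
    keep = np.asarray(out.counts, dtype=float) >= T
    out.weights = np.where(keep, out.weights, 0.0)
    out.counts = np.where(keep, out.counts, 0)
    out.metadata["count_threshold"] = int(T)
    return out


def graph_density(g: Connectome | BinaryGraph) -> float:
    """Fraction of possible undirected edges that are present.

    rho = E / (N(N-1)/2) for a simple undirected graph on N >= 2 nodes.
    """
    n = g.n_nodes
    if n < 2:
        raise ValueError("graph density requires at least 2 nodes")
    return g.n_edges / (n * (n - 1) / 2)


def largest_component(c: Connectome) -> Connectome:
    """Restrict a connectome to its largest connected component.

    Used by path metrics when the caller opts into the ``largest``
    disconnected-graph policy instead of the default hard error.
    """
    n_comp, membership = connected_components(
        sp.csr_matrix(c.weights > 0), directed=False
    )
    if n_comp <= 1:
        return c.copy()
    sizes = np.bincount(membership)
    keep = np.flatnonzero(membership == np.argmax(sizes))
    out = Connectome(
        node_labels=[c.node_labels[i] for i in keep],
        weights=c.weights[np.ix_(keep, keep)],
        counts=None if c.counts is None else c.counts[np.ix_(keep, keep)],
        metadata=dict(c.metadata, component="largest"),
    )
    logger.info(
        "restricted to largest component: %d of %d nodes", len(keep), c.n_nodes
    )
    return out


def symmetrize(matrix: np.ndarray, what: str = "matrix") -> np.ndarray:
    """Average A and A.T when the asymmetry is numerically negligible.

    Diffusion-derived networks are undirected by construction, so any
    asymmetry in a numeric input is round-off.  Beyond ``SYMMETRY_RTOL``
    (relative to the largest magnitude) it is treated as corrupt data.
    """
    matrix = np.asarray(matrix, dtype=float)
    gap = np.abs(matrix - matrix.T).max() if matrix.size else 0.0
    scale = np.abs(matrix).max() if matrix.size else 0.0
    if gap == 0:
        return matrix
    if scale > 0 and gap <= SYMMETRY_RTOL * scale:
        logger.warning("symmetrized %s (max asymmetry %.3g)", what, gap)
        return (matrix + matrix.T) / 2.0
    raise ConnectomeError(
        f"{what} is asymmetric beyond tolerance (max |a_ij - a_ji| = {gap:.3g})"
    )
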