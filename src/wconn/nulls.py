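"""Null-hypothesis networks preserving degree sequence and weight multiset.

A binary null keeps the node count and the exact degree sequence of the
source network while randomizing which pairs are connected (Maslov-
Sneppen double-edge swaps).  A weighted null additionally reuses the
source's edge weights: the weight list is randomly permuted onto the
rewired edges, so the weight distribution of source and null are
identical as multisets, not merely in expectation.  Comparing clustering
and path length against such nulls isolates topology-plus-weight-placement
effects from degree and weight-distribution effects.
"""

from __future__ import annotations

import hashlib
import logging
from dataclasses import dataclass, field

import numpy as np

from .core import BinaryGraph, Connectome, binarize, require_valid

logger = logging.getLogger("wconn")


@dataclass
class NullModelConfig:
    """Randomization parameters.

    swaps_per_edge:
        Attempted double-edge swaps per edge (Maslov-Sneppen burn-in);
        10 is the customary mixing budget.
    n_replicates:
        Null networks per source.  One replicate mirrors the original
        once-per-session practice; 20 or more is recommended for stable
        null means.
    rng_seed:
        Seed for all randomness; recorded in every replicate's metadata.
    """

    swaps_per_edge: int = 10
    n_replicates: int = 1
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.swaps_per_edge < 1 or self.n_replicates < 1:
            raise ValueError("swaps_per_edge and n_replicates must be positive")


@dataclass
class NullEnsemble:
    """Replicate nulls plus the fingerprint of the source they conserve."""

    n_nodes: int
    degree_sequence: tuple[int, ...]
    weight_multiset_hash: str
    replicates: list[Connectome] = field(default_factory=list)
    config: NullModelConfig | None = None


def _weight_hash(weights: np.ndarray) -> str:
    return hashlib.sha256(np.sort(weights).tobytes()).hexdigest()[:16]


def _edge_set(adj: np.ndarray) -> list[tuple[int, int]]:
    iu, ju = np.triu_indices(adj.shape[0], k=1)
    present = adj[iu, ju] > 0
    return list(zip(iu[present].tolist(), ju[present].tolist()))


def _rewire(adj: np.ndarray, n_attempts: int, rng: np.random.Generator) -> np.ndarray:
    """Attempted double-edge swaps on a copied 0/1 adjacency.

    Each attempt picks two distinct edges (a, b), (c, d), randomly
    orients the second, and proposes (a, d), (c, b).  Proposals creating
    self-loops or duplicate edges are rejected, so the graph stays simple
    and every node keeps its exact degree.  Rigid graphs (e.g. complete
    graphs or triangles) admit no legal swap and come back unchanged.
    """
    adj = adj.copy()
    edges = _edge_set(adj)
    m = len(edges)
    if m < 2:
        logger.info("fewer than 2 edges: nothing to rewire")
        return adj
    successes = 0
    for _ in range(n_attempts):
        e1, e2 = rng.choice(m, size=2, replace=False)
        a, b = edges[e1]
        c, d = edges[e2]
        if rng.random() < 0.5:
            c, d = d, c
        if a == d or c == b or len({a, b, c, d}) < 4:
            continue
        if adj[a, d] or adj[c, b]:
            continue
        adj[a, b] = adj[b, a] = 0
        adj[c, d] = adj[d, c] = 0
        adj[a, d] = adj[d, a] = 1
        adj[c, b] = adj[b, c] = 1
        edges[e1] = (min(a, d), max(a, d))
        edges[e2] = (min(c, b), max(c, b))
        successes += 1
    if successes == 0:
        logger.info("no legal double-edge swap found; graph returned unchanged")
    return adj


def rewire_degree_preserving(g: BinaryGraph, cfg: NullModelConfig) -> BinaryGraph:
    """Degree-preserving randomization of a binary graph.

    Performs ``swaps_per_edge * E`` attempted double-edge swaps.  The
    output has the same node count and the exact same degree sequence as
    the input, and is deterministic for a fixed config.
    """
    e = g.n_edges
    if e < 2:
        raise ValueError("rewiring requires at least 2 edges")
    rng = np.random.default_rng(cfg.rng_seed)
    adj = _rewire(g.adjacency, cfg.swaps_per_edge * e, rng)
    return BinaryGraph(node_labels=list(g.node_labels), adjacency=adj)


def assign_weights_from_source(
    null_g: BinaryGraph, source: Connectome, rng_seed: int
) -> Connectome:
    """Permute the source's edge weights onto a rewired topology.

    Weights are drawn without replacement, so the output's weight
    multiset equals the source's exactly.  Null networks are abstract
    randomizations, so no streamline-count matrix is attached.
    """
    rng = np.random.default_rng(rng_seed)
    return _assign_weights(null_g, source, rng)


def _assign_weights(
    null_g: BinaryGraph, source: Connectome, rng: np.random.Generator
) -> Connectome:
    src_weights = source.edge_weight_list()
    pairs = _edge_set(null_g.adjacency)
    if len(pairs) != len(src_weights):
        raise ValueError(
            f"edge-count mismatch: null graph has {len(pairs)} edges, "
            f"source has {len(src_weights)}"
        )
    n = null_g.n_nodes
    w = np.zeros((n, n))
    permuted = rng.permutation(src_weights)
    for (i, j), wij in zip(pairs, permuted):
        w[i, j] = w[j, i] = wij
    return require_valid(
        Connectome(
            node_labels=list(null_g.node_labels),
            weights=w,
            metadata={"null_model": "degree+weight-preserving"},
        )
    )


def generate_null_ensemble(c: Connectome, cfg: NullModelConfig) -> NullEnsemble:
    """Build ``n_replicates`` nulls of a connectome, reproducibly.

    Each replicate rewires the binarized source and permutes the source
    weights onto the result, using independent sub-streams derived
    deterministically from ``cfg.rng_seed``.  Every replicate conserves
    the node count, the degree sequence, and the weight multiset.
    """
    g = binarize(c)
    if g.n_edges < 2:
        raise ValueError("null models require at least 2 edges")
    degrees = tuple(int(x) for x in np.sort(g.adjacency.sum(axis=1)))
    ensemble = NullEnsemble(
        n_nodes=c.n_nodes,
        degree_sequence=degrees,
        weight_multiset_hash=_weight_hash(c.edge_weight_list()),
        config=cfg,
    )
    attempts = cfg.swaps_per_edge * g.n_edges
    children = np.random.SeedSequence(cfg.rng_seed).spawn(cfg.n_replicates)
    for rep, child in enumerate(children):
        rng = np.random.default_rng(child)
        adj = _rewire(g.adjacency, attempts, rng)
        null_g = BinaryGraph(node_labels=list(g.node_labels), adjacency=adj)
        null_c = _assign_weights(null_g, c, rng)
        null_c.metadata.update(rng_seed=cfg.rng_seed, replicate=rep)
        ensemble.replicates.append(null_c)
    return ensemble
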