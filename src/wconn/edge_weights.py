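"""Dimensionless edge weights from streamline geometry.

The weight of the edge between parcels i and j is built from the set R of
tractography streamlines whose two termination points lie in i and j::

    w(e_ij) = (V_voxel / P_voxel) * (2 / (A_i + A_j)) * sum_{f in R} 1 / l(f)

where V_voxel is the voxel volume (mm^3), P_voxel the number of seed
points per voxel, A_i and A_j the parcel surface areas (mm^2), and l(f)
the streamline length (mm).  The V/P prefactor removes the dependence on
the seeding paradigm, the inverse length removes the dependence on bundle
length (for equal-length streamlines the sum counts fibers), and the
surface-area normalization removes parcel-size bias.  Dimensionally,
mm^3 * mm^-2 * mm^-1 cancels, so the weight is a pure number and is
invariant under a uniform rescaling of the anatomy (lengths x s, areas
x s^2, volumes x s^3).
"""

from __future__ import annotations

import logging
from collections import defaultdict
from dataclasses import dataclass, field

import numpy as np

from .core import Connectome, require_valid

logger = logging.getLogger("wconn")


@dataclass
class StreamlineRecord:
    """One tractography streamline: seed, length, and node endpoints.

    ``node_a``/``node_b`` are the parcels containing the two termination
    points; either may be None for streamlines that end outside every
    parcel (such streamlines belong to no edge).  ``seed_in_node`` marks
    streamlines whose seed voxel lies inside one of their endpoint
    parcels; those can be excluded as likely artifacts of seeding inside
    gray matter rather than genuine white-matter paths.
    """

    stream_id: str
    seed_voxel: int
    length_mm: float
    node_a: str | None
    node_b: str | None
    seed_in_node: bool = False

    def __post_init__(self) -> None:
        if self.length_mm <= 0:
            raise ValueError(
                f"streamline {self.stream_id!r}: length must be positive, "
                f"got {self.length_mm}"
            )
        if self.node_a is not None and self.node_a == self.node_b:
            raise ValueError(
                f"streamline {self.stream_id!r}: both endpoints in node "
                f"{self.node_a!r} (self-edges are undefined)"
            )


@dataclass
class ParcellationSpec:
    """Geometry of the parcellation and seeding scheme.

    voxel_volume_mm3 : V, volume of one MR voxel.
    seeds_per_voxel  : P, tractography seeds launched per voxel.
    surface_areas_mm2: parcel label -> surface area A.
    """

    voxel_volume_mm3: float
    seeds_per_voxel: int
    surface_areas_mm2: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.voxel_volume_mm3 <= 0:
            raise ValueError("voxel volume must be positive")
        if self.seeds_per_voxel < 1:
            raise ValueError("seeds per voxel must be a positive integer")
        for lab, a in self.surface_areas_mm2.items():
            if a <= 0:
                raise ValueError(f"surface area of node {lab!r} must be positive")

    def area(self, label: str) -> float:
        try:
            return self.surface_areas_mm2[label]
        except KeyError:
            raise KeyError(f"no surface area for node {label!r}") from None


def characteristic_filter(
    streams: list[StreamlineRecord],
    i: str,
    j: str,
    exclude_seed_in_node: bool = True,
) -> list[StreamlineRecord]:
    """Select the streamline set R connecting parcels ``i`` and ``j``.

    Keeps exactly the streamlines whose endpoint pair is {i, j} in either
    order.  With ``exclude_seed_in_node`` set, streamlines seeded inside
    one of their own endpoint parcels are filtered out.  Streamlines with
    a missing endpoint belong to no edge and are skipped (their number is
    logged once per call).
    """
    if i == j:
        raise ValueError(f"self-edge ({i!r}, {i!r}) is undefined")
    wanted = {i, j}
    dangling = 0
    out = []
    for s in streams:
        if s.node_a is None or s.node_b is None:
            dangling += 1
            continue
        if {s.node_a, s.node_b} != wanted:
            continue
        if exclude_seed_in_node and s.seed_in_node:
            continue
        out.append(s)
    if dangling:
        logger.debug("ignored %d streamline(s) with a missing endpoint", dangling)
    return out


def edge_weight(
    R: list[StreamlineRecord],
    spec: ParcellationSpec,
    i: str,
    j: str,
) -> float:
    """Weight of edge (i, j) from its retained streamline set R.

    R must already be filtered for the pair (use
    :func:`characteristic_filter`).  Returns 0 for an empty R.
    """
    a_i, a_j = spec.area(i), spec.area(j)
    inv_lengths = 0.0
    for s in R:
        if s.length_mm <= 0:
            raise ValueError(f"streamline {s.stream_id!r} has non-positive length")
        inv_lengths += 1.0 / s.length_mm
    return (
        (spec.voxel_volume_mm3 / spec.seeds_per_voxel)
        * (2.0 / (a_i + a_j))
        * inv_lengths
    )


def build_connectome(
    streams: list[StreamlineRecord],
    spec: ParcellationSpec,
    node_labels: list[str],
    exclude_seed_in_node: bool = True,
) -> Connectome:
    """Assemble a weighted+counted connectome from a streamline table.

    For every unordered parcel pair the edge count is |R(i, j)| and the
    edge weight is :func:`edge_weight` over that set.  Streamlines
    referencing a label outside ``node_labels`` are an error; streamlines
    with a missing endpoint are skipped.
    """
    labels = [str(x) for x in node_labels]
    if len(set(labels)) != len(labels):
        raise ValueError("node labels must be unique")
    idx = {lab: k for k, lab in enumerate(labels)}
    n = len(labels)

    groups: dict[tuple[int, int], list[StreamlineRecord]] = defaultdict(list)
    dangling = 0
    for s in streams:
        if s.node_a is None or s.node_b is None:
            dangling += 1
            continue
        for lab in (s.node_a, s.node_b):
            if lab not in idx:
                raise KeyError(
                    f"streamline {s.stream_id!r} references unknown node {lab!r}"
                )
        if exclude_seed_in_node and s.seed_in_node:
            continue
        a, b = sorted((idx[s.node_a], idx[s.node_b]))
        groups[(a, b)].append(s)
    if dangling:
        logger.info("ignored %d streamline(s) with a missing endpoint", dangling)

    w = np.zeros((n, n))
    k = np.zeros((n, n), dtype=np.int64)
    for (a, b), R in groups.items():
        w[a, b] = w[b, a] = edge_weight(R, spec, labels[a], labels[b])
        k[a, b] = k[b, a] = len(R)
    return require_valid(
        Connectome(labels, w, k, metadata={"source": "streamlines",
                                           "n_streamlines": len(streams)})
    )


def max_possible_streamlines(M_voxels: int, spec: ParcellationSpec) -> int:
    """Ceiling on the streamline count of an edge spanning ``M_voxels`` voxels.

    With P seeds per voxel, at most M x P streamlines can make up the
    bundle; the ratio threshold/ceiling is how count thresholds are
    reasoned about (e.g. 25 of a 250-streamline ceiling retains edges with
    at least 10% of the smallest plausible bundle).
    """
    if M_voxels < 1 or int(M_voxels) != M_voxels:
        raise ValueError("M_voxels must be a positive integer")
    return int(M_voxels) * spec.seeds_per_voxel
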