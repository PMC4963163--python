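"""Reading and writing connectomes and streamline tables.

Three interchange formats are supported, all plain text:

``csv_matrix``
    First row: comma-separated node labels.  Then N rows of N reals.
    One file per matrix role (weights or counts); ``role="both"`` takes a
    second path for the counts matrix.
``edge_list``
    Tab-separated ``node_a  node_b  weight  count`` with a header row;
    each undirected edge appears once in either orientation.
``graphml``
    Undirected GraphML with edge attributes ``weight`` (double) and
    ``count`` (long) and node attribute ``label``.
"""

from __future__ import annotations

import logging
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd

from .core import Connectome, ConnectomeError, require_valid, symmetrize
from .edge_weights import ParcellationSpec, StreamlineRecord

logger = logging.getLogger("wconn")

FORMATS = ("csv_matrix", "edge_list", "graphml")


class ParseError(ConnectomeError):
    """Malformed input file; the message names the offending cell or row."""


def _clean_diagonal(m: np.ndarray, what: str) -> np.ndarray:
    if np.any(np.diag(m) != 0):
        logger.warning("forcing nonzero %s diagonal to zero", what)
        m = m.copy()
        np.fill_diagonal(m, 0)
    return m


def _read_csv_matrix(path: Path, what: str) -> tuple[list[str], np.ndarray]:
    df = pd.read_csv(path, header=0)
    labels = [str(c) for c in df.columns]
    m = df.to_numpy(dtype=float)
    if m.shape[0] != m.shape[1] or m.shape[1] != len(labels):
        raise ParseError(
            f"{path}: matrix is {m.shape[0]}x{m.shape[1]} but header lists "
            f"{len(labels)} labels (must be square)"
        )
    if np.any(~np.isfinite(m)):
        i, j = np.argwhere(~np.isfinite(m))[0]
        raise ParseError(f"{path}: non-finite entry at row {i + 1}, column {labels[j]}")
    m = symmetrize(m, f"{what} matrix from {path}")
    return labels, _clean_diagonal(m, what)


def _check_counts(m: np.ndarray, origin: str) -> np.ndarray:
    if np.any(m < 0):
        i, j = np.argwhere(m < 0)[0]
        raise ParseError(f"{origin}: negative count at ({i}, {j})")
    if not np.array_equal(m, np.round(m)):
        i, j = np.argwhere(m != np.round(m))[0]
        raise ParseError(f"{origin}: non-integer count {m[i, j]!r} at ({i}, {j})")
    return m.astype(np.int64)


def load_connectome(
    path: str | Path,
    format: str = "csv_matrix",
    role: str = "weights",
    counts_path: str | Path | None = None,
) -> Connectome:
    """Load a connectome from one of the supported text formats.

    ``role`` states which matrices the input carries: ``weights``,
    ``counts`` (weights are set equal to the counts so the network is
    usable on its own), or ``both``.  For ``csv_matrix`` with
    ``role="both"``, ``counts_path`` names the counts file.
    """
    path = Path(path)
    if format not in FORMATS:
        raise ValueError(f"unknown format {format!r}; expected one of {FORMATS}")
    if role not in ("weights", "counts", "both"):
        raise ValueError(f"unknown role {role!r}")

    if format == "csv_matrix":
        labels, m = _read_csv_matrix(path, "weights" if role != "counts" else "counts")
        if role == "weights":
            c = Connectome(labels, m)
        elif role == "counts":
            k = _check_counts(m, str(path))
            c = Connectome(labels, k.astype(float), k)
        else:
            if counts_path is None:
                raise ValueError("role='both' with csv_matrix requires counts_path")
            labels2, m2 = _read_csv_matrix(Path(counts_path), "counts")
            if labels2 != labels:
                raise ParseError("weights and counts files disagree on node labels")
            c = Connectome(labels, m, _check_counts(m2, str(counts_path)))
    elif format == "edge_list":
        c = _load_edge_list(path, role)
    else:
        c = _load_graphml(path, role)
    if np.any(c.weights < 0):
        i, j = np.argwhere(c.weights < 0)[0]
        raise ParseError(f"{path}: negative weight at ({c.node_labels[i]}, {c.node_labels[j]})")
    c.metadata.setdefault("source", str(path))
    c.metadata.setdefault("format", format)
    return require_valid(c)


def _load_edge_list(path: Path, role: str) -> Connectome:
    df = pd.read_csv(path, sep="\t", header=0, dtype={"node_a": str, "node_b": str})
    need = {"node_a", "node_b", "weight"} | ({"count"} if role != "weights" else set())
    missing = need - set(df.columns)
    if missing:
        raise ParseError(f"{path}: missing column(s) {sorted(missing)}")
    labels = sorted(set(df["node_a"]) | set(df["node_b"]))
    idx = {lab: i for i, lab in enumerate(labels)}
    n = len(labels)
    w = np.zeros((n, n))
    k = np.zeros((n, n), dtype=np.int64) if "count" in df.columns else None
    seen: dict[tuple[int, int], tuple] = {}
    for row_no, row in enumerate(df.itertuples(index=False), start=2):
        a, b = idx[row.node_a], idx[row.node_b]
        if a == b:
            raise ParseError(f"{path}: self-edge on row {row_no} ({row.node_a})")
        key = (min(a, b), max(a, b))
        val = (float(row.weight), getattr(row, "count", None))
        if key in seen:
            if seen[key] != val:
                raise ParseError(
                    f"{path}: row {row_no} conflicts with an earlier row for "
                    f"edge ({row.node_a}, {row.node_b})"
                )
            continue
        seen[key] = val
        w[a, b] = w[b, a] = float(row.weight)
        if k is not None:
            cnt = float(row.count)
            if cnt != round(cnt):
                raise ParseError(f"{path}: non-integer count on row {row_no}")
            k[a, b] = k[b, a] = int(round(cnt))
    if role == "counts" and k is not None:
        w = k.astype(float)
    return Connectome(labels, w, k)


def _load_graphml(path: Path, role: str) -> Connectome:
    g = nx.read_graphml(path)
    if g.is_directed():
        raise ParseError(f"{path}: connectomes are undirected; got a directed graph")
    nodes = list(g.nodes())
    labels = [str(g.nodes[v].get("label", v)) for v in nodes]
    order = np.argsort(labels, kind="stable")
    nodes = [nodes[i] for i in order]
    labels = [labels[i] for i in order]
    idx = {v: i for i, v in enumerate(nodes)}
    n = len(nodes)
    w = np.zeros((n, n))
    have_counts = any("count" in d for _, _, d in g.edges(data=True))
    k = np.zeros((n, n), dtype=np.int64) if have_counts else None
    for u, v, d in g.edges(data=True):
        a, b = idx[u], idx[v]
        if a == b:
            raise ParseError(f"{path}: self-edge on node {labels[a]}")
        w[a, b] = w[b, a] = float(d.get("weight", 1.0))
        if k is not None:
            k[a, b] = k[b, a] = int(d.get("count", 0))
    if role == "counts" and k is not None:
        w = k.astype(float)
    return Connectome(labels, w, k)


def save_connectome(c: Connectome, path: str | Path, format: str = "csv_matrix") -> None:
    """Write a connectome so that :func:`load_connectome` round-trips it.

    Weights survive to double precision, counts and labels exactly.  For
    ``csv_matrix`` the counts matrix, when present, is written next to the
    weights file with a ``.counts.csv`` suffix.
    """
    path = Path(path)
    if format == "csv_matrix":
        pd.DataFrame(c.weights, columns=c.node_labels).to_csv(
            path, index=False, float_format="%.17g"
        )
        if c.counts is not None:
            pd.DataFrame(c.counts, columns=c.node_labels).to_csv(
                counts_companion(path), index=False
            )
    elif format == "edge_list":
        rows = []
        for i, j in c.edge_pairs():
            row = {
                "node_a": c.node_labels[i],
                "node_b": c.node_labels[j],
                "weight": c.weights[i, j],
            }
            if c.counts is not None:
                row["count"] = int(c.counts[i, j])
            rows.append(row)
        cols = ["node_a", "node_b", "weight"] + (["count"] if c.counts is not None else [])
        pd.DataFrame(rows, columns=cols).to_csv(
            path, sep="\t", index=False, float_format="%.17g"
        )
    elif format == "graphml":
        g = nx.Graph()
        for lab in c.node_labels:
            g.add_node(lab, label=lab)
        for i, j in c.edge_pairs():
            attrs = {"weight": float(c.weights[i, j])}
            if c.counts is not None:
                attrs["count"] = int(c.counts[i, j])
            g.add_edge(c.node_labels[i], c.node_labels[j], **attrs)
        nx.write_graphml(g, path)
    else:
        raise ValueError(f"unknown format {format!r}; expected one of {FORMATS}")


def counts_companion(weights_path: str | Path) -> Path:
    """Companion counts file for a csv_matrix weights file."""
    p = Path(weights_path)
    return p.with_suffix(".counts.csv")


# -- streamline tables and parcellation files ----------------------------


def load_streamlines(path: str | Path) -> list[StreamlineRecord]:
    """Read a tab-separated streamline table.

    Columns: ``stream_id  seed_voxel  length_mm  node_a  node_b
    seed_in_node``; an empty node field means the streamline terminated
    outside every node.
    """
    df = pd.read_csv(path, sep="\t", header=0, keep_default_na=False,
                     dtype={"node_a": str, "node_b": str})
    need = {"stream_id", "seed_voxel", "length_mm", "node_a", "node_b", "seed_in_node"}
    missing = need - set(df.columns)
    if missing:
        raise ParseError(f"{path}: missing column(s) {sorted(missing)}")
    records = []
    for row_no, row in enumerate(df.itertuples(index=False), start=2):
        length = float(row.length_mm)
        if length <= 0:
            raise ParseError(f"{path}: non-positive length on row {row_no}")
        records.append(
            StreamlineRecord(
                stream_id=str(row.stream_id),
                seed_voxel=int(row.seed_voxel),
                length_mm=length,
                node_a=str(row.node_a) or None,
                node_b=str(row.node_b) or None,
                seed_in_node=str(row.seed_in_node).strip().lower() in ("1", "true", "yes"),
            )
        )
    return records


def save_streamlines(streams: list[StreamlineRecord], path: str | Path) -> None:
    pd.DataFrame(
        {
            "stream_id": [s.stream_id for s in streams],
            "seed_voxel": [s.seed_voxel for s in streams],
            "length_mm": [s.length_mm for s in streams],
            "node_a": [s.node_a or "" for s in streams],
            "node_b": [s.node_b or "" for s in streams],
            "seed_in_node": [int(s.seed_in_node) for s in streams],
        }
    ).to_csv(path, sep="\t", index=False, float_format="%.17g")


def load_parcellation(path: str | Path) -> ParcellationSpec:
    """Read a key-value parcellation file.

    Lines: ``voxel_volume_mm3=<v>``, ``seeds_per_voxel=<p>`` and one
    ``area:<label>=<mm2>`` per node.  Blank lines and ``#`` comments are
    ignored.
    """
    volume = seeds = None
    areas: dict[str, float] = {}
    for line_no, raw in enumerate(Path(path).read_text().splitlines(), start=1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        if "=" not in line:
            raise ParseError(f"{path}: line {line_no} is not key=value")
        key, val = (s.strip() for s in line.split("=", 1))
        if key == "voxel_volume_mm3":
            volume = float(val)
        elif key == "seeds_per_voxel":
            seeds = int(val)
        elif key.startswith("area:"):
            areas[key[len("area:"):]] = float(val)
        else:
            raise ParseError(f"{path}: unknown key {key!r} on line {line_no}")
    if volume is None or seeds is None:
        raise ParseError(f"{path}: voxel_volume_mm3 and seeds_per_voxel are required")
    return ParcellationSpec(voxel_volume_mm3=volume, seeds_per_voxel=seeds,
                            surface_areas_mm2=areas)


def save_parcellation(spec: ParcellationSpec, path: str | Path) -> None:
    lines = [
        f"voxel_volume_mm3={spec.voxel_volume_mm3:.17g}",
        f"seeds_per_voxel={spec.seeds_per_voxel}",
    ]
    lines += [f"area:{lab}={a:.17g}" for lab, a in sorted(spec.surface_areas_mm2.items())]
    Path(path).write_text("\n".join(lines) + "\n")
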