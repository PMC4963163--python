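"""Threshold-sweep reports: metrics across count thresholds and modes.

Each run writes one TSV per report section into an output directory,
plus a plain-text manifest recording the configuration, seed and input
fingerprint, so a run can be reproduced byte for byte.
"""

from __future__ import annotations

import hashlib
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .core import Connectome, apply_count_threshold, binarize, graph_density
from .metrics import (
    binary_geodesics,
    clustering,
    cumulative_distribution,
    mean_geodesic,
    node_degree,
    node_strength,
    weighted_geodesics,
)
from .nulls import NullModelConfig, generate_null_ensemble
from .smallworld import small_worldness

logger = logging.getLogger("wconn")

DEFAULT_THRESHOLDS = (0, 25, 50, 125)
DEFAULT_MODES = ("binary", "onnela", "zhang")


@dataclass
class RunConfig:
    """Configuration of a full threshold-sweep analysis."""

    thresholds: tuple[int, ...] = DEFAULT_THRESHOLDS
    modes: tuple[str, ...] = DEFAULT_MODES
    null_replicates: int = 20
    seed: int = 0
    out_dir: str | Path = "wconn_report"
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        ts = tuple(int(t) for t in self.thresholds)
        if sorted(set(ts)) != list(ts):
            raise ValueError("thresholds must be sorted ascending and unique")
        self.thresholds = ts


def threshold_difference(c: Connectome, T1: int, T2: int) -> pd.DataFrame:
    """Edges removed when the count threshold rises from T1 to T2.

    Rows cover every edge present at threshold T1 (count >= T1), with
    status ``removed`` for counts in [T1, T2) and ``kept`` otherwise.
    """
    if T1 > T2:
        raise ValueError(f"thresholds out of order: T1={T1} > T2={T2}")
    if c.counts is None:
        raise ValueError("threshold difference requires streamline counts")
    rows = []
    for i, j in c.edge_pairs():
        cnt = int(c.counts[i, j])
        if cnt < T1:
            continue
        rows.append(
            {
                "node_a": c.node_labels[i],
                "node_b": c.node_labels[j],
                "count": cnt,
                "weight": c.weights[i, j],
                "status": "removed" if cnt < T2 else "kept",
            }
        )
    return pd.DataFrame(rows, columns=["node_a", "node_b", "count", "weight", "status"])


def _fingerprint(c: Connectome) -> str:
    h = hashlib.sha256()
    h.update(np.ascontiguousarray(c.weights).tobytes())
    if c.counts is not None:
        h.update(np.ascontiguousarray(c.counts).tobytes())
    return h.hexdigest()[:16]


def run_full_analysis(c: Connectome, cfg: RunConfig) -> dict[str, Path]:
    """Compute the full threshold x mode report for one connectome.

    Writes, per threshold: long-form node metrics (degree, strength,
    mean geodesics, clusterings), cumulative degree/strength
    distributions, and the edge-difference table against the lowest
    threshold.  Across thresholds and modes: density and the
    small-worldness table (gamma, lambda, sw with null dispersions).
    Returns the written paths keyed by section name.
    """
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written: dict[str, Path] = {}

    density_rows = []
    sw_rows = []
    node_rows = []
    cum_rows = []
    for T in cfg.thresholds:
        logger.info("threshold %d: computing metrics", T)
        ct = apply_count_threshold(c, T) if c.counts is not None or T > 0 else c.copy()
        g = binarize(ct)
        density_rows.append({"threshold": T, "density": graph_density(g),
                             "n_edges": g.n_edges})

        deg = node_degree(g)
        stren = node_strength(ct)
        vectors = [deg, stren]
        bin_paths = binary_geodesics(g)
        w_paths = weighted_geodesics(ct)
        if bin_paths.is_connected():
            vectors.append(mean_geodesic(bin_paths))
            vectors.append(mean_geodesic(w_paths))
        else:
            logger.warning("threshold %d disconnects the graph; "
                           "path metrics omitted", T)
        for mode in cfg.modes:
            vectors.append(clustering(ct, mode))
        for vec in vectors:
            for lab, val in zip(vec.node_labels, vec.values):
                node_rows.append({"threshold": T, "node": lab,
                                  "metric": vec.name, "value": val})
        for vec in (deg, stren):
            cum = cumulative_distribution(vec)
            for row in cum.itertuples(index=False):
                cum_rows.append({"threshold": T, "metric": vec.name,
                                 "value": row.value, "fraction": row.fraction})

        ncfg = NullModelConfig(n_replicates=cfg.null_replicates,
                               rng_seed=cfg.seed + T)
        if bin_paths.is_connected():
            ensemble = generate_null_ensemble(ct, ncfg)
            for mode in cfg.modes:
                r = small_worldness(ct, mode, ncfg, ensemble=ensemble)
                sw_rows.append(
                    {"threshold": T, "mode": mode, "c_g": r.c_g, "l_g": r.l_g,
                     "c_N": r.c_N, "l_N": r.l_N, "gamma": r.gamma,
                     "lambda": r.lam, "sw": r.sw, "n_null": r.n_null,
                     "sd_c_N": r.sd_c_N, "sd_l_N": r.sd_l_N}
                )

    def _write(name: str, df: pd.DataFrame) -> None:
        path = out / f"{name}.tsv"
        df.to_csv(path, sep="\t", index=False, float_format="%.12g")
        written[name] = path

    _write("density", pd.DataFrame(density_rows))
    _write("node_metrics", pd.DataFrame(node_rows))
    _write("cumulative_distributions", pd.DataFrame(cum_rows))
    if sw_rows:
        _write("small_worldness", pd.DataFrame(sw_rows))
    if c.counts is not None and len(cfg.thresholds) > 1:
        diff = threshold_difference(c, cfg.thresholds[0], cfg.thresholds[-1])
        _write("threshold_difference", diff)

    manifest = out / "run_manifest.txt"
    manifest.write_text(
        "\n".join(
            [
                f"wconn_version={__version__}",
                f"seed={cfg.seed}",
                f"thresholds={','.join(map(str, cfg.thresholds))}",
                f"modes={','.join(cfg.modes)}",
                f"null_replicates={cfg.null_replicates}",
                f"n_nodes={c.n_nodes}",
                f"n_edges={c.n_edges}",
                f"input_fingerprint={_fingerprint(c)}",
            ]
        )
        + "\n"
    )
    written["run_manifest"] = manifest
    return written
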