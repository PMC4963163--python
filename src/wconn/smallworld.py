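"""Small-worldness of binary and weighted connectomes.

A network is small-world when it is more clustered than a comparable
random network while keeping similarly short geodesics.  With c_g and l_g
the network-average clustering and geodesic length of the source and
c_N, l_N those of a matched null ensemble,

    gamma = c_g / c_N,    lambda = l_g / l_N,    sw = gamma / lambda,

and small-world organization is gamma > 1 with lambda ~ 1, hence sw > 1.
Three modes are supported: ``binary`` (triangle clustering, hop-count
paths), ``onnela`` and ``zhang`` (the respective weighted clustering with
max-weight-sum min-hop paths).  A mode's gamma and lambda always come
from the same framework; binary clustering is never mixed with weighted
paths.  For weighted modes no inversion is applied to lambda even though
larger d^w means a stronger path, so weighted lambda typically falls
below 1 for networks whose strong edges are better placed than chance.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import Connectome
from .metrics import CLUSTERING_MODES, clustering, geodesics, mean_geodesic
from .nulls import NullEnsemble, NullModelConfig, generate_null_ensemble


@dataclass
class SmallWorldResult:
    """gamma, lambda and sw for one mode, with the null summary behind them."""

    mode: str
    c_g: float
    l_g: float
    c_N: float
    l_N: float
    gamma: float
    lam: float
    sw: float
    n_null: int
    sd_c_N: float
    sd_l_N: float


def network_average_clustering(c: Connectome, mode: str) -> float:
    """Mean over all N nodes of the mode's clustering coefficient."""
    return float(np.mean(clustering(c, mode).values))


def network_average_path(c: Connectome, mode: str) -> float:
    """Mean over all nodes of the mean geodesic length (hop or weighted)."""
    return float(np.mean(mean_geodesic(geodesics(c, mode)).values))


def small_worldness(
    c: Connectome,
    mode: str,
    cfg: NullModelConfig,
    ensemble: NullEnsemble | None = None,
) -> SmallWorldResult:
    """Evaluate gamma, lambda and sw against a null ensemble.

    The null ensemble preserves the source's degree sequence and weight
    multiset; c_N and l_N are means over its replicates (pass a
    pre-built ``ensemble`` to share nulls across modes).  Degenerate
    nulls (zero mean clustering or path length) raise rather than
    returning infinities.
    """
    if mode not in CLUSTERING_MODES:
        raise ValueError(f"unknown mode {mode!r}; expected one of {CLUSTERING_MODES}")
    c_g = network_average_clustering(c, mode)
    l_g = network_average_path(c, mode)
    if ensemble is None:
        ensemble = generate_null_ensemble(c, cfg)
    c_null = np.array(
        [network_average_clustering(r, mode) for r in ensemble.replicates]
    )
    l_null = np.array([network_average_path(r, mode) for r in ensemble.replicates])
    c_N, l_N = float(c_null.mean()), float(l_null.mean())
    if c_N <= 0 or l_N <= 0:
        raise ValueError(
            f"degenerate null ensemble (c_N={c_N}, l_N={l_N}); "
            "gamma/lambda are undefined"
        )
    gamma = c_g / c_N
    lam = l_g / l_N
    return SmallWorldResult(
        mode=mode,
        c_g=c_g,
        l_g=l_g,
        c_N=c_N,
        l_N=l_N,
        gamma=gamma,
        lam=lam,
        sw=gamma / lam,
        n_null=len(ensemble.replicates),
        sd_c_N=float(c_null.std(ddof=1)) if len(c_null) > 1 else 0.0,
        sd_l_N=float(l_null.std(ddof=1)) if len(l_null) > 1 else 0.0,
    )
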