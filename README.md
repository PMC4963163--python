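# wconn — weighted connectome analysis

`wconn` analyzes dense, weighted structural brain networks of the kind
produced by diffusion-MRI tractography: each node is a gray-matter parcel,
each edge carries both a streamline count and a dimensionless connection
weight. It is written for researchers who want to compare the **binary**
view of a connectome (an edge exists or it does not) with the **weighted**
view (edges differ in strength), in particular for topology measures such
as small-worldness that are notoriously sensitive to graph density and to
arbitrary edge thresholds.

## The framework

**Edge weight.** From the streamline set *R* connecting parcels *i* and *j*,

```
w(e_ij) = (V_voxel / P_voxel) · (2 / (A_i + A_j)) · Σ_{f∈R} 1 / l(f)
```

with voxel volume *V* (mm³), seeds per voxel *P*, parcel surface areas
*A_i*, *A_j* (mm²) and streamline lengths *l(f)* (mm). The weight is
dimensionless and invariant under uniform anatomical rescaling, and the
*V/P* prefactor removes the dependence on the seeding paradigm.

**Thresholding** acts on the streamline count, never the weight, so the
same cut applies to both views: an edge survives threshold *T* iff its
bundle has ≥ *T* streamlines.

**Metrics.** Degree *k_i* and strength *s_i*; hop-count geodesics *d_ij*
and the weighted "low-cost" geodesic *d^w_ij* — among all minimum-hop
paths, the one with the **highest** edge-weight sum; binary clustering
*c_i*, Onnela clustering *c_{i,O}* (geometric-mean triangle intensities,
degree-normalized) and Zhang–Horvath clustering *c_{i,Z}* (fully
weight-normalized), all on weights scaled by the network maximum.

**Null models** preserve the node count, the exact degree sequence
(double-edge-swap rewiring) and — for weighted analyses — the exact edge
weight multiset (permutation without replacement).

**Small-worldness.** With network averages *c_g*, *l_g* and null averages
*c_N*, *l_N*:  γ = c_g/c_N, λ = l_g/l_N, sw = γ/λ. Small-world
organization means γ > 1 with λ ≈ 1, hence sw > 1.

## Worked example

```python
import numpy as np
import wconn

# a dense synthetic connectome: 68 nodes, ~51% density, log-normal weights
c = wconn.generate_connectome(wconn.SynthConfig(rng_seed=1))
print(f"density {wconn.graph_density(c):.3f}, edges {c.n_edges}")

# count-threshold at the 40th percentile: degree collapses, strength doesn't
counts = c.counts[np.triu_indices(c.n_nodes, 1)]
T = int(np.percentile(counts[counts > 0], 40))
ct = wconn.apply_count_threshold(c, T)
deg0 = wconn.node_degree(wconn.binarize(c)).values.mean()
deg1 = wconn.node_degree(wconn.binarize(ct)).values.mean()
s0 = wconn.node_strength(c).values.mean()
s1 = wconn.node_strength(ct).values.mean()
print(f"mean degree {deg0:.1f} -> {deg1:.1f}, mean strength {s0:.4f} -> {s1:.4f}")

# weighted small-worldness survives density that washes out the binary view
sw_net = wconn.generate_smallworld_reference(seed=0)   # ~51% density
cfg = wconn.NullModelConfig(n_replicates=10, rng_seed=7)
ens = wconn.generate_null_ensemble(sw_net, cfg)
for mode in ("binary", "zhang"):
    r = wconn.small_worldness(sw_net, mode, cfg, ensemble=ens)
    print(f"{mode:6s} gamma={r.gamma:.2f} lambda={r.lam:.2f} sw={r.sw:.2f}")
```

prints

```
density 0.510, edges 1162
mean degree 34.2 -> 20.9, mean strength 0.6711 -> 0.6688
binary gamma=1.24 lambda=1.00 sw=1.24
zhang  gamma=3.39 lambda=0.66 sw=5.13
```

Mean degree drops ~40% under the threshold while mean strength moves by
~0.3%: the weighted description is threshold-stable. On the ~50%-dense
weighted small-world benchmark the binary framework sees sw ≈ 1.2 (high
density hides the lattice structure) while the Zhang-mode weighted
framework sees sw ≈ 5: weighted small-worldness survives graph density.

The same pipeline is scriptable from the shell:

```bash
wconn simulate connectome --seed 1 --out c.graphml
wconn smallworld --in c.graphml --mode binary,zhang --thresholds 0,25,50,125 \
      --null-replicates 20 --seed 7 --out sw.tsv
wconn report --in c.graphml --out-dir report/
```

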