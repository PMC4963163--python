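# Methods

## Data model

A connectome is a simple undirected graph on N labeled nodes with two
edge attributes: a non-negative real weight and a non-negative integer
streamline count. Diffusion-derived connectivity is antipodally
symmetric, so only undirected graphs are represented; both matrices are
symmetric with zero diagonal, and an edge exists iff its weight is
strictly positive (counts, when present, must be positive exactly
there). Asymmetric numeric input is averaged with its transpose when the
asymmetry is below 1e-12 relative to the largest entry (round-off), and
rejected otherwise. File formats (CSV matrix, TSV edge list, GraphML)
identify nodes by label only; positional indices are internal.

## Edge weight

The weight of edge (i, j) from its retained streamline set R is

    w(e_ij) = (V/P) · (2/(A_i + A_j)) · Σ_{f∈R} 1/l(f)

with V the voxel volume (mm³), P the seeds per voxel, A the parcel
surface areas (mm²), l the streamline lengths (mm). The inverse-length
sum makes the weight count fibers for equal-length bundles and cancels
the length dimension; dimensionally mm³·mm⁻²·mm⁻¹ = 1, so the weight is
a pure number and invariant under uniform rescaling of the anatomy
(lengths ×s, areas ×s², volumes ×s³) — a property the test suite checks
to 1e-12. The characteristic filter retains exactly the streamlines
whose two termination parcels are {i, j}, optionally excluding
streamlines seeded inside one of their own endpoint parcels (a common
artifact of gray-matter seeding). Streamlines with a missing endpoint
belong to no edge and are skipped with a logged tally. Imaging-specific
voxel filtering (e.g. excluding voxels off the white-matter path) is
upstream of this package: the caller's endpoint assignment is trusted.

## Thresholding

Thresholds are applied to streamline counts, inclusively (an edge
survives threshold T iff count ≥ T), never to weights: the count is a
tractography-support measure, and one cut then applies identically to
the binary and the weighted view. With a weights-only network, count
thresholding raises instead of silently falling back to weight cuts.
Thresholding is monotone (edge sets shrink as T grows) and commutes with
binarization; both properties are tested.

## Geodesics

Binary geodesics are hop counts (breadth-first search). The weighted
geodesic between i and j is defined over the *minimum-hop* paths only:
among all paths with exactly h_ij = d_ij edges, d^w_ij is the largest
total edge weight. Hop count has absolute priority — a weak direct edge
beats a strong two-hop detour — so a step along the geodesic is always
the strongest available connection at the minimal number of
synaptic-like relays. The implementation sweeps hop layers outward from
each source: best(v, h) = max over neighbors u at layer h−1 of
best(u, h−1) + w(u, v). A walk of exactly h edges ending at hop
distance h cannot revisit a node (a revisit would waste at least two
edges), so the layered recursion is exact; the test suite confirms exact
agreement with exhaustive path enumeration on hundreds of small graphs.
Ties in path identity are irrelevant since only the maximal sum is
returned. Unreachable pairs are marked NaN; mean-geodesic aggregation
raises on a disconnected graph by default (silently averaging finite
entries would bias comparisons), and `largest_component` is provided
for callers who prefer restriction to the giant component.

## Clustering

All three coefficients are computed from ordered-neighbor-pair sums over
the weights scaled by the network-wide maximum (ŵ = w / max w, computed
on the network as currently thresholded — each analyzed network is
self-contained):

* binary: c_i = Σ a_ij a_jm a_mi / (k_i (k_i − 1));
* Onnela: same normalization, triangle terms (ŵ_ij ŵ_jm ŵ_mi)^{1/3},
  with k_i the binary degree of the thresholded network;
* Zhang: Σ ŵ_ij ŵ_jm ŵ_mi / ((Σ_j ŵ_ij)² − Σ_j ŵ_ij²).

Nodes with degree ≤ 1 (or a vanishing Zhang denominator) get c = 0, the
standard convention preserving the [0, 1] range. When all weights are
equal both weighted variants reduce to the binary coefficient, checked
to 1e-12.

## Null models

A null network preserves (1) the node count, (2) the exact degree
sequence, and — for weighted analyses — (3) the exact multiset of edge
weights. Topology is randomized by attempted double-edge swaps
(10 × E attempts by default, the customary Maslov–Sneppen burn-in;
proposals creating self-loops or duplicate edges are rejected, and rigid
graphs such as complete graphs come back unchanged with a logged
notice). Weights are then permuted onto the rewired edges *without
replacement*: a permutation is the only scheme that preserves the weight
distribution exactly rather than in expectation. Replicates use
independent sub-streams spawned deterministically from one seed; an
ensemble records the source fingerprint (N, degree sequence, weight-list
hash) and every replicate is checked against it in the tests.

## Small-worldness

γ = c_g/c_N, λ = l_g/l_N, sw = γ/λ, with c_N and l_N means over the
null ensemble's replicates. One replicate mirrors the historical
once-per-network practice and is the config default; 20 replicates are
used in the reports and recommended, since single-null estimates are
noisy. A result's γ and λ always come from the same mode — binary
clustering is never mixed with weighted paths. For weighted modes λ is
l_g/l_N exactly as defined, with no inversion despite larger d^w meaning
a *stronger* path; on weight-clustered networks this puts weighted λ
below 1, and sw = γ/λ then amplifies rather than cancels the clustering
excess. Degenerate nulls (c_N or l_N = 0) raise explicitly.

## Synthetic data

The generators reproduce the statistical regime of dense single-subject
tractography networks, not anatomy. What passing tests show is that the
pipeline behaves correctly in that regime; they say nothing about
tractography accuracy, registration error, or any particular brain.

* **Dense connectome**: uniform-random topology with exactly
  round(ρ·N(N−1)/2) edges (defaults N = 68, ρ = 0.51); i.i.d. log-normal
  weights, median 1e-3, ln-sd 2.4. The bulk of weights spans roughly
  1e-6 to 1e-1 (several orders of magnitude); the ln-sd is set so the
  weakest 40% of edges carry well under 1% of total weight, matching the
  observed near-invariance of node strength under count thresholding in
  real dense connectomes. Counts follow round(600·w^0.32) with
  multiplicative log-normal noise (sd 0.1), floored at 1; the exponent
  and scale are calibrated analytically so a count cutoff at ~10% of the
  maximum removes ~40% of edges (the ~51% → ~30% density drop of a
  125-streamline threshold), yielding median counts near 65 and maxima
  near 550 so that thresholds of 25/50/125 are meaningful. Optional
  block communities multiply within-block weights by a boost factor
  (default 8), giving weight-clustered structure that permutation nulls
  destroy.
* **Small-world reference**: Watts–Strogatz ring lattice (defaults
  n = 68, k = 34 ⇒ ~51% density, p_rewire = 0.1). "neighborhood-strong"
  weighting decays log-linearly with ring distance between the endpoints
  (contrast 1e4 across the half-ring, scale 0.05, ln-jitter 0.2), so the
  strongest edges concentrate inside clustered neighborhoods while
  shortcuts are weak — the configuration in which weighted clustering
  towers over its weight-permuted null while binary clustering at 50%
  density barely exceeds chance. Uniform weighting (all 1.0) gives the
  exact binary limit.
* **Streamline fixtures**: requested bundles of equal-length streamlines
  with closed-form expected weights (V/P)·(2/(A_i+A_j))·(n/l).
* **Session replicates**: multiplicative weight jitter with total CV
  9.4% split into a network-wide session factor (80% of variance;
  scanner state and registration shift all edges together) and
  independent per-edge noise (20%) — without the shared factor,
  averaging over a node's ~34 edges would shrink node-strength CV well
  below the scan-rescan level. Each replicate additionally drops a
  half-normal-sized random subset of weakest-quartile edges, sized so
  the across-replicate density CV is ~3.6%. The toggling mechanism is a
  statistical stand-in matching printed variability levels, not a model
  of acquisition physics.

All generators are deterministic under a fixed seed and their outputs
pass the full invariant validator.

## Problem sizes and numerics

Oracle comparisons use exhaustive enumeration on graphs of N ≤ 8 (200
cases) and triple-loop clustering sums on N = 15; the small-world suites
use 20 seeds with 10–20 null replicates at N = 68, sizes at which the
layered geodesic recursion and matrix-product clustering are exact and
fast. Equality tolerances are 1e-12 for algebraic identities and exact
for integer-valued quantities (degree sequences, counts, edge sets).
Reports round to 12 significant digits; determinism of every pipeline
stage under a fixed seed is itself a tested property.

## Known limitations

The package does not perform tractography, registration or parcellation,
and trusts the caller's streamline-to-parcel endpoint assignment. Only
count-based sparsification is implemented (no backbone pruning,
efficiency, betweenness, modularity or rich-club measures).
Strength-preserving weighted configuration nulls and spatially embedded
nulls are out of scope. The synthetic weight law is a modeling choice:
any heavy-tailed law spanning the observed range would serve, and
conclusions about real data should not lean on its specific form.
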