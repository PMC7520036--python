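# Methods

## Model

A cell–cell communication analysis produces, for every interacting pair
(ligand–receptor couple or unordered partner pair), a square non-negative
weight matrix over a fixed ordered list of N cell types.  `comunetx` treats
each matrix as the adjacency matrix of a directed weighted graph — row =
sender (ligand / partner-1 expresser), column = receiver (receptor /
partner-2 expresser) — and stacks the graphs as layers of a multiplex
network.  Edges exist iff their weight is strictly positive (upstream tools
already zero out non-significant interactions, so no epsilon threshold is
applied).  Self-edges (autocrine signalling) are allowed, enter all edge
sets and dissimilarity sums, and contribute nothing to the node balance.
Empty (all-zero) layers are rejected at construction: the dissimilarity of
two empty layers would be 0/0.

Per node, the balance Δ = weighted out-degree − weighted in-degree is
positive for predominant senders and negative for predominant receivers;
the sign convention is fixed so that it matches the red/blue semantics of
the figures.  Δ is linear in the weights and sums to zero over the nodes of
a layer.  In floating point the per-node values are correctly rounded row /
column sums, so the computed total is zero only to within a few ulps; the
test suite asserts conservation exactly in rational arithmetic and bounds
the float total by 1e−9.  Δ is reported in the raw units of the upstream
scores, with no normalisation by node count or total weight.

## Dissimilarity

For layers α, β over the same cell types:

d(α,β) = Σ_{ij} s_{ij} / |E_α ∪ E_β| with s_{ij} = |w^α_{ij} − w^β_{ij}| /
(w^α_{ij} + w^β_{ij}) where at least one weight is positive and 0 where both
vanish.  The per-cell condition is deliberately "at least one positive"
rather than "product non-zero": under the product reading two edge-disjoint
layers would score 0 (identical), which contradicts the measure's role as a
modified Jaccard *distance*.  With the adopted convention d ∈ [0,1], d = 0
iff the matrices agree on the union of their edge sets, d = 1 iff the edge
sets are disjoint, d is invariant under a common positive rescaling of both
layers, and on binarized layers it equals the classical Jaccard distance of
directed edge sets.  The union counts directed cell-type pairs, including
self-pairs.  The pairwise matrix is computed once per unordered pair and
mirrored, so symmetry and the zero diagonal hold exactly.

## Clustering

Layers are clustered by average-linkage (UPGMA) hierarchical clustering of
the dissimilarity matrix (scipy; equal-height tie-breaks follow scipy's
deterministic lowest-index order) and cut with a Dynamic Hybrid procedure
(defaults `deep_split = 0`, `min_cluster_size = 6`).  The cut walks the
merge tree bottom-up and declares a branch a cluster when it (i) has at
least `min_cluster_size` members, (ii) has a tight core, and (iii) is
separated from its surroundings by a gap between its attachment height and
its core scatter.  Definitions used here:

- the *core* of a branch of size m is its `min_cluster_size // 2 + 1 +
  sqrt(m − …)` earliest-attaching members (members are ordered by the height
  at which they joined the branch lineage; absorbed sub-branch members keep
  their original joining heights);
- *core scatter* is the mean pairwise dissimilarity among core members;
- thresholds are expressed relative to the height range between a reference
  height (5th percentile of merge heights) and the cut height (default 99%
  of the top merge): with q = deep_split/4, the relative scatter ceiling is
  0.64 + 0.31 q and the minimum relative gap (1 − ceiling) · 3/4, linearly
  interpolating from the most conservative setting at 0 to the most
  sensitive at 4.

When two candidate branches meet below the cut height and both qualify,
both are committed as clusters; if only one qualifies it absorbs the other;
if neither does they fuse and keep growing.  Branches still open at the cut
height are evaluated with the cut height as attachment.  Objects never
committed keep label 0 (unassigned) and are then assigned, PAM-like, to the
cluster with the smallest average dissimilarity provided that average is
below the cut height; clusters are numbered 1..K by decreasing size.  The
reference implementation of this algorithm family interpolates its
constants from `deepSplit` in the same spirit; the interpolation used here
is this package's own parameterization, chosen to be most conservative at
0, and is validated behaviourally (planted separable instances must come
out exactly; instances smaller than the minimum cluster size must stay
fully unassigned) rather than constant-for-constant.

Each cluster is summarised by the arithmetic mean of its members' weight
matrices and Δ vectors; by linearity the mean Δ equals Δ of the mean
matrix, which the tests assert for every cluster.  Unassigned layers are
excluded from averages and reported separately.

The optional 2-D embedding runs UMAP on the precomputed dissimilarity
matrix (`n_neighbors = min(15, L−1)`, fixed `random_state`, single job) and
falls back to classical metric MDS when UMAP is not importable; the method
actually used is returned alongside the coordinates, and both paths are
deterministic for a fixed seed.

## Pattern search and comparison

A pattern query is a binary adjacency matrix with at least one edge.  Every
layer is binarized to its support and compared with the query using the
same dissimilarity (hence the Jaccard distance of directed edge sets);
weights never influence the ranking, and the output is sorted ascending
with lexicographic pair-id tie-breaks.  All layers are returned; filtering
is left to the caller.

The two-condition comparison requires identical ordered cell-type sets,
matches layers by exact pair id (whitespace-trimmed), computes the
*weighted* dissimilarity per shared pair (comparison cares about weight
changes, not just rewiring) and sorts descending.  Pairs present in only
one condition are reported separately rather than scored: conflating
"absent" with "maximally changed" is a modelling choice the user must make
explicitly (`exclusive_as_max=True` / `--exclusive-as-max` applies the
d = 1 convention).  No significance threshold for a "dramatic" change is
provided; the ranking is the result.

## Synthetic data

The generator plants K distinct binary archetypes over N cell types and
emits `members_per_archetype` layers per archetype: each cell of the
archetype is flipped independently with probability `edge_flip_prob`
(symmetric present↔absent flips, keeping expected density stable) and
present edges draw lognormal weights (defaults μ = 0, σ = 0.5, mimicking
positive right-skewed mean-expression scores).  A member left edge-less by
the flips is redrawn, which is rare at the default density and does not
noticeably bias the realised flip rate (checked against 3σ binomial bounds
in the tests).  Defaults used across the test suite and the acceptance
script: N = 6 cell types, archetype density 0.3, 6–10 members per
archetype, 10% flips — small enough to run in seconds, large enough that
clusters can satisfy the minimum-size criterion.  `perturb_network` moves a
chosen fraction of a layer's edges to cells empty both now and originally,
so a fully rewired layer is edge-disjoint from (d = 1 to) its original.

What the synthetic data does *not* emulate: correlated edge noise (real
dropout is gene- and cell-type-structured, not i.i.d.), heavy-tailed and
interaction-specific weight scales, nested or overlapping communication
programmes, and upstream significance-testing artefacts.  Passing the
planted-recovery tests therefore shows the pipeline recovers block
structure of the stated strength under i.i.d. noise — not that real
datasets cluster this cleanly.

## Numerical and design choices

- Exact comparisons where exactness is structural (symmetry, zero diagonal,
  d = 1 for disjoint supports — IEEE division gives w/w = 1 exactly);
  1e−12 tolerances for algebraic identities; 1e−10 against the O(L³) UPGMA
  oracle.
- Dissimilarity matrices are validated on construction (symmetry, zero
  diagonal, range within [0, 1] ± 1e−12).
- CSV/TSV writers emit 17-significant-digit floats and readers parse with
  round-trip precision, so tabular round trips are bit-stable.
- CellPhoneDB dialects: `significant_means` (missing = not significant) and
  `means` + `pvalues` (keep mean where p ≤ threshold, default 0.05).  Which
  upstream column is the canonical weight is not asserted; both dialects
  are offered.  Multi-subunit complexes are opaque partner labels.
- The clustering step is exposed as a scikit-learn-compatible estimator
  (`HybridTreeCut`) so it composes with sklearn model-selection tooling;
  the rest of the pipeline is plain functions over typed containers.

## Limitations

- The Dynamic Hybrid constants are a faithful-in-spirit parameterization,
  not a constant-level port; on borderline branches its labels can differ
  from other implementations of the same algorithm family.
- With strongly overlapping archetypes (support Jaccard similarity ≳ 0.3)
  and ≥ 10% noise, adjacent archetypes can be fused at `deep_split = 0`;
  raising `deep_split` trades this against over-splitting.
- UMAP on very small layer sets (L ≲ 10) is dominated by its neighbourhood
  size; the MDS fallback is often the more honest picture there.
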