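# Methods

## Problem setting

Given an ordered collection of rooted, labelled phylogenetic trees on one
shared tip-label set, the package (i) maps each tree to a metric feature
vector, (ii) computes the pairwise tree-distance matrix, (iii) embeds the
collection in a low-dimensional Euclidean space by metric MDS (principal
coordinate analysis), (iv) partitions it into "tree islands" by
hierarchical clustering, and (v) summarises each island by its geometric
median tree. The design assumption throughout is that topological
incongruence between trees manifests as geometric structure — distinct
clusters — in the embedded landscape.

## Tree metrics

All vector metrics index tip pairs in one canonical order:
lexicographically sorted labels, pairs `(i, j)` with `label_i < label_j`
in `itertools.combinations` order. Any fixed order yields identical
distances; sorting makes vectors comparable across trees and output
columns stable.

**Kendall–Colijn (`kc`).** For each tip pair, `m_ij` = number of edges on
the root→MRCA(i, j) path and `M_ij` = branch-length sum on that path; the
vector ends with n per-tip slots equal to 1 in `m` and to the pendant
branch length in `M`. The returned vector is
`v_λ = (1 − λ)·m + λ·M`. The MRCA of a pair whose MRCA is the root has
depth 0. The per-tip slots are constant in `m` and therefore cancel in
λ = 0 distances; they are kept for fidelity to the published vector
definition. Preconditions: a bifurcating root (under a basal polytomy the
root→MRCA edge count is ill-defined, and such trees are rejected with a
clear error), and branch lengths on every edge when λ > 0. Non-root
multifurcations are accepted — MRCA depths remain well defined — though a
reference implementation operating strictly on binary trees might differ
there. Default λ = 0 (pure topology), exposed as `--lambda` on the CLI.

**Path difference (`path`, `path_l1`).** Entry (i, j) = number of edges
between tips i and j *in the tree as given*: the root node of a rooted
tree counts as a path node, matching the worked 3-tip example
((A,B),C) → (2, 3, 3). `path` uses the L2 norm, `path_l1` the L1 variant.

**Abouheif (`abouheif`) and sum of direct descendants (`sum_dd`).** For
the internal nodes on the path between tips i and j — the nodes strictly
between each tip and the MRCA, plus the MRCA itself — take the product
(Abouheif) or sum (`sum_dd`) of each node's child count. Both use the
same path-node set; on ((A,B),C) the A–C path crosses two bifurcations,
giving 2 × 2 = 4 (product) and 2 + 2 = 4 (sum). Purely topological;
multifurcation child counts are used as-is.

**Branch score (`branch_score`).** Sparse map from each bipartition
(split) to its branch length, under the unrooted convention: the two
edges below a bifurcating root induce the same split and their lengths
add. Trivial (single-tip) splits are included — pendant lengths matter.
Distance = L2 norm over the union of splits, 0 for absent splits.
Splits are encoded as bitmasks over the canonical label order,
canonicalized to the side not containing the first label. Agrees with
phangorn's `KF.dist` to 1e-10 (cross-checked by test).

**Robinson–Foulds (`rf`).** Size of the symmetric difference of the
non-trivial unrooted split sets — the raw count (phangorn `RF.dist`
convention), not halved or normalized. For a whole collection the matrix
is computed as L1 distances between 0/1 split-indicator rows over the
union of splits, which is entrywise identical to the per-pair set
computation.

Matrix computation is vectorized: feature vectors are stacked and handed
to `scipy.spatial.distance.pdist`. Dense storage; collections of 10²–10⁴
trees fit comfortably in memory.

## Landscape embedding

PCoA: Gower double-centring of `−D²/2`, symmetric eigendecomposition,
coordinates = eigenvectors × √eigenvalue, axes in descending eigenvalue
order. Numerical choices:

- eigenvalues within ±1e-10 of 0 are treated as exactly 0;
- a distance matrix counts as non-Euclidean when its most negative
  centred eigenvalue is below −1e-8 × the largest one — only then is the
  Cailliez correction applied (the threshold is a package choice, exposed
  through `is_euclidean`);
- requesting more axes than there are positive eigenvalues truncates with
  a warning rather than an error;
- axis signs are fixed by forcing the largest-magnitude loading positive,
  so repeated runs (and hence output files) are byte-identical;
- default 3 retained axes, overridable.

The Cailliez constant is the largest real eigenvalue of the 2n × 2n
companion matrix `[[0, 2Δ₁], [−I, −4Δ₂]]` with Δ₁ the centred `−D²/2` and
Δ₂ the centred `−D/2`; it is added to every off-diagonal entry. Tests
verify minimality (c − 10⁻³ leaves a negative eigenvalue) and agreement
of the embedding with scikit-bio's independent PCoA.

Scree proportions are relative to the sum of *positive* eigenvalues only.

## Island detection

Agglomerative clustering (scipy) with single, complete, UPGMA (= average)
or Ward linkage, cut to exactly k groups with `cut_tree`. Ward operates
on condensed distances (the ward.D2-style criterion), coherent with the
Euclidean embedding. The default clustering basis is the retained MDS
coordinates; clustering on the raw distance matrix is a flag away. Labels
are renumbered 1..k by first appearance in tree order, making partitions
deterministic and permutation-stable. k is always user-supplied — a
silhouette-score helper (`silhouette_profile`) assists choosing k by
inspection but is never applied automatically.

## Median trees

Per island: mean of the members' `v_λ` vectors, then median = all member
trees at minimal Euclidean distance to that mean (exact float equality;
identical topologies at λ = 0 produce bit-identical distances, so ties
are found reliably). All co-minimal trees are reported; file output
writes the lowest index. The mean vector is never converted back to a
tree. Medians are defined via the Kendall–Colijn vector only; weighted
means are a possible extension, not implemented.

## Synthetic data

`random_tree` draws a rooted binary tree by uniform sequential
pair-joining (labels `t1..tn`, branch lengths i.i.d. exponential).
`nni_perturb` applies nearest-neighbour interchanges on internal edges of
the *unrooted* tree — the two edges below the root count as one merged
edge — because an exchange across an edge incident to a degree-2 root
merely re-roots the tree. Each move therefore replaces exactly one
non-trivial split: one move ⇒ RF distance 2, and island "tightness" is
controlled in RF units. Lengths of edges touched by a move are redrawn.

`make_islands` draws base topologies until pairwise RF ≥ 4 (preventing
accidental island overlap; error after 1000 failed draws), then emits
NNI-perturbed members. Benchmark defaults — 4 islands × 50 trees, 20
tips, 2 NNI moves per member, exponential(1) lengths — are the study
conditions used by the acceptance checks; a scientist would read them as
a modest posterior-sample-sized collection with pronounced, but not
caricatural, topological clustering. All randomness flows from a single
numpy Generator seeded once.

What the generator does *not* emulate: branch lengths carry no clock or
rate structure (i.i.d. exponential), islands are equally sized and
equally tight, and there is no phylogenetic signal linking branch lengths
to topology. Passing the recovery benchmark therefore demonstrates that
the pipeline separates topologically distinct clusters; it does not
certify behaviour on landscapes whose islands differ mainly in branch
lengths, overlap heavily, or have long-tailed size distributions.

## Interfaces and determinism

Newick (quoted labels, internal-node labels, exponent-notation lengths)
and NEXUS (TRANSLATE tables) input via dendropy; Newick output with 15
significant digits on lengths, which keeps distance matrices across a
write/read round trip within 1e-9 (9 digits would not). Tabular outputs
are TSV with `%.10g` floats; every CLI run writes a `provenance.json`
(configuration + library versions). Identical configuration and seed
reproduce every output file byte-for-byte.

The sklearn-style estimators (`TreeVectorizer`, `PCoA`, `IslandFinder`)
wrap the same functions with `fit`/`transform`/`get_params` conventions;
for split-based metrics the vectorizer's column basis is the union of
splits in the fitted collection, so transforming a collection with unseen
splits is rejected rather than silently misaligned.

## Known limitations

- The Billera–Holmes–Vogtmann geodesic metric is not implemented (it has
  no vector representation and needs a dedicated geodesic algorithm);
  the metric registry is the extension point.
- No automatic choice of k, λ or the number of axes.
- Nonlinear embeddings (t-SNE and kin) are out of scope; for strongly
  non-Euclidean metrics (RF) the linear MDS picture can distort island
  boundaries even after Cailliez correction.
- `median_trees` is O(islands × members × vector length); for 10⁴-tree
  collections with hundreds of tips, vector construction dominates and
  is currently single-threaded.
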