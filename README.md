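# phylolandscape

Statistical exploration of landscapes of phylogenetic trees.

Phylogenetic analyses rarely end with a single tree: bootstrap replicates,
Bayesian posterior samples and competing inference methods each produce
whole collections of rooted, labelled trees over the same taxa, and those
collections are often *incongruent* — several distinct topologies can be
nearly equally supported by the data. `phylolandscape` is a toolkit for
making that incongruence visible and quantifiable, for anyone who works
with sets of trees (posterior samples, gene trees, bootstrap forests):

1. **Tree metrics** — each tree is mapped to a feature vector and pairwise
   tree-to-tree distances are computed. The centrepiece is the
   Kendall–Colijn metric: for each tip pair (i, j) the vector records
   m<sub>ij</sub>, the number of edges from the root to MRCA(i, j), and
   M<sub>ij</sub>, the branch-length sum on that path, blended as
   v<sub>λ</sub>(T) = (1 − λ)·m(T) + λ·M(T) with λ ∈ [0, 1] (λ = 0 is
   purely topological). Also implemented: Robinson–Foulds, branch score
   (Kuhner–Felsenstein), path difference (L2 and L1), Abouheif's
   dissimilarity, and sum of direct descendants.
2. **Landscape** — metric MDS / principal coordinate analysis projects the
   distance matrix into a low-dimensional Euclidean space. Non-Euclidean
   distances (e.g. Robinson–Foulds) are first made Euclidean by the
   Cailliez correction, the smallest additive constant on off-diagonal
   entries.
3. **Tree islands** — hierarchical clustering (single, complete, UPGMA or
   Ward linkage) of the projected landscape identifies clusters of
   mutually similar topologies.
4. **Median trees** — each island is summarised by its geometric median
   tree(s): the member tree(s) whose Kendall–Colijn vector is closest to
   the island's mean vector. The median is always an actual tree from the
   sample, so it never exhibits artefacts such as negative branch lengths.

A synthetic-data module generates random trees and island-structured
collections with known ground truth, so the entire pipeline is testable
without any external data.

## Worked example

```python
import phylolandscape as pl
from sklearn.metrics import adjusted_rand_score

# simulate four islands of 50 trees each (20 tips, 2 NNI moves per tree)
coll, truth = pl.make_islands(pl.IslandSpec(seed=42))

dm   = pl.distance_matrix(coll, metric="kc", lam=0.0)   # step 1
emb  = pl.pcoa(dm, n_axes=3)                            # step 2
part = pl.find_islands(emb, k=4, linkage="ward")        # step 3
meds = pl.median_trees(coll, part, lam=0.0)             # step 4

print(f"cailliez constant: {emb.cailliez_constant}")
print(f"variance on first 3 axes: {pl.scree(emb)[:3].round(3)}")
print(f"ARI vs generating islands: {adjusted_rand_score(truth, part.labels)}")
for r in meds:
    print(f"island {r.island_id}: {len(r.member_indices)} trees, "
          f"median = {coll.names[r.median_indices[0]]}")
```

prints

```
cailliez constant: 0.0
variance on first 3 axes: [0.418 0.293 0.189]
ARI vs generating islands: 1.0
island 1: 50 trees, median = island1_tree1
island 2: 50 trees, median = island2_tree14
island 3: 50 trees, median = island3_tree29
island 4: 50 trees, median = island4_tree33
```

The Cailliez constant is 0 because Kendall–Colijn distances are Euclidean
by construction (they are norms of vector differences); the three leading
axes carry 90% of the landscape's variance; Ward clustering on the
3-D coordinates recovers the four generating islands exactly (adjusted
Rand index 1.0), and each island is summarised by one of its own members.

Estimator-style classes (`TreeVectorizer`, `PCoA`, `IslandFinder`) expose
the same stages with the scikit-learn `fit` / `transform` /
`get_params` conventions.

### Command line

The same pipeline is available from the shell; all outputs are plain text
(TSV / Newick / JSON) plus a `provenance.json` sidecar that records the
exact configuration:

```sh
phylolandscape simulate --tips 20 --islands 4 --per-island 50 --seed 42 --outdir sim/
phylolandscape pipeline sim/trees.nwk --metric kc --lambda 0 --axes 3 \
    --linkage ward --k 4 --outdir run/
```

Subcommands: `dist`, `mds`, `islands`, `median`, `simulate`, `pipeline`.
Input is Newick (one tree per `;`) or NEXUS (TRANSLATE tables supported);
all trees must share one tip-label set.

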