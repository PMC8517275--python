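# treecoclust

Tree-constrained co-clustering of binary chromatin-accessibility matrices.

Bulk ATAC-seq across many related cell types — hematopoietic cell types
descending from a common stem cell, for example — is usually summarised as a
binary accessibility matrix **M**: one row per genomic locus, one column per
cell type, with M<sub>lc</sub> = 1 when locus *l* was called accessible in
cell type *c*.  The scientific question this package addresses is how the
structure of M reflects the *differentiation tree* over the cell types: do
loci that open together do so across coherent branches of the tree, and how
much of the cell-type-associated variation in accessibility can a modest
number of tree-coherent cell-type groups explain?

`treecoclust` is aimed at computational epigenomics groups who have
per-cell-type peak calls and a known differentiation hierarchy and want a
quantitative, reproducible decomposition of accessibility variation along
that hierarchy.

## The method

1. **Matrix construction.**  Each peak contributes a 500 bp window centred
   on its summit.  Windows from all cell types are reduced per chromosome,
   5'→3', to a greedy master list of non-overlapping loci (highest summit
   quality score wins among intersecting windows).  M<sub>lc</sub> = 1 iff
   any original peak of cell type *c* overlaps master locus *l*.  Loci
   accessible in ≤ 2 cell types ("cell-specific") are set aside.
2. **Locus clustering.**  Rows are nodes of a similarity graph.  For rows
   with *n* and *N* ones out of *C* columns sharing *s* ones, *s* is
   referred to a hypergeometric null (population *C*, *N* successes, *n*
   draws) — the null of permuting one row's columns.  Edges are placed at a
   Benjamini–Hochberg FDR over all row pairs, and communities are found
   with the Louvain algorithm.  Clusters with ≥ 30 loci move forward.
3. **Cell-type clustering.**  A cell-type set *respects* the tree when it is
   connected, or when the roots of its connected components are all
   children of one parent.  A k-way partition into respecting clusters is
   encoded by k−1 *cut groups* (a cut vertex *p* plus a subset of its
   children whose edges are severed).  The partition minimising
   ‖M − M̃(k)‖²_F — where M̃(k) replaces every (locus cluster × cell
   cluster) co-cluster by its mean — is sought by greedy local search over
   cut-group and cut-vertex moves with 20 random restarts.  Ward
   hierarchical and k-means column clusterings are available as
   tree-agnostic baselines.
4. **Two-state model and ANOVA.**  Per locus cluster the co-cluster means
   are optionally restricted to two values (inaccessible/accessible); the
   exact optimum is a weighted 1-D 2-means over sorted means.  An ANOVA
   decomposition reports R²_total (variation of M captured by M̃) and
   R²_celltype (variation of the column means captured by the column
   clustering), averaged over locus clusters.
5. **Enrichment.**  Each locus cluster plus its accessible cell types forms
   an *accessibility co-cluster*.  A motif's score is
   (r − n)/(r + n), where *r* is the motif frequency among the co-cluster's
   accessible (TSS-distal) loci averaged over its cell types, and *n* is
   the same quantity on the complement; a permutation of the motif
   matrix's locus labels calibrates a score cutoff at a target FDR.
   ChIP-seq summits are counted per locus cluster, scaled by a
   uniform-placement expectation, and the overlap between ChIP-enriched
   and accessible clusters is tested hypergeometrically.

## Worked example

Synthetic data with planted structure (30 cell types, 5 planted cell
clusters, 8 locus clusters of 250 loci each, Bernoulli rates 0.8/0.05):

```python
import numpy as np
from treecoclust import (SyntheticSpec, simulate_dataset, build_graph,
                         louvain_partition, optimize, fit_means, anova)

ds = simulate_dataset(SyntheticSpec(seed=3))
mask = ds.clustered_mask                # drop cell-specific loci
M, labels = ds.M[mask], ds.row_labels[mask]

graph = build_graph(M, fdr=0.05)
rows = louvain_partition(graph, seed=0)
print(f"connected fraction {graph.connected_fraction:.3f}, "
      f"top cluster sizes {rows.sizes[:8]}")

run = optimize(M, labels, ds.tree, k=5, restarts=20, seed=0)
print(f"best SSE {run.best_sse:.1f}; planted partition recovered: "
      f"{run.best_partition.as_key() == ds.partition.as_key()}")

cols = np.array(run.best_partition.labels(ds.tree.nodes))
model = fit_means(M, labels, cols)
res = anova(M, labels, cols, model)
print(f"R2_total {res.overall_r2_total:.3f}, "
      f"R2_celltype {res.overall_r2_celltype:.3f}")
```

prints

```
connected fraction 0.888, top cluster sizes [274 257 249 223 217 205 171 156]
best SSE 6365.4; planted partition recovered: True
R2_total 0.445, R2_celltype 0.996
```

The eight largest recovered locus clusters track the planted ones (250
loci each; a few loci land in small noise communities); the
tree-constrained search recovers the planted 5-way cell partition exactly;
the co-cluster model then captures ≈ 45% of the total variation but
essentially all of the cell-type-associated variation — the gap is
within-co-cluster Bernoulli noise, which no column clustering can
explain.

The same workflow is available from the shell:

```sh
treecoclust simulate --n-cells 30 --k 5 --j 8 --rows 250 --seed 3 --out-prefix sim
treecoclust cluster-loci --matrix sim.matrix.tsv --edge-fdr 0.05 --out-prefix sim
treecoclust cluster-celltypes --matrix sim.matrix.tsv --row-clusters sim.row_clusters.tsv \
    --tree sim.tree.tsv --k 5 --restarts 20 --seed 0 --out-prefix sim
treecoclust anova --matrix sim.matrix.tsv --row-clusters sim.row_clusters.tsv \
    --col-clusters sim.col_clusters.tsv --two-state --out-prefix sim
```

`build-matrix` (narrowPeak input), `motif-enrich` and `chip-assoc` cover the
remaining stages; every stage writes a JSON manifest and is skipped when
rerun with identical inputs.

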