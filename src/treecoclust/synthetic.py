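"""Synthetic differentiation trees and planted co-cluster accessibility data.

The generator emulates the structure observed in real multi-cell-type
ATAC-seq accessibility matrices: loci fall into clusters, each locus
cluster is in one of two accessibility states per cell-type cluster, the
cell-type clusters form a tree-respecting partition of a differentiation
tree, entries are Bernoulli draws whose rate depends only on the state, and
a sizeable fraction of loci are cell-specific (accessible in 1-2 cell
types).  Optionally a binary motif matrix is generated with one motif
planted at a target locus cluster's loci.

All randomness flows from a single seed through named substreams (tree,
partition, states, entries, cell_specific, motifs), so each component is
independently reproducible and regeneration is bit-exact.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .enrichment import MotifHitMatrix
from .tree_model import CutSpec, DifferentiationTree, TreePartition, partition_from_cutspec

__all__ = [
    "SyntheticSpec",
    "SyntheticDataset",
    "random_tree",
    "random_cutspec",
    "simulate_matrix",
    "simulate_motifs",
    "simulate_dataset",
]

_STREAMS = ("tree", "partition", "states", "entries", "cell_specific", "motifs")


def _substream(seed: int, name: str) -> np.random.Generator:
    return np.random.default_rng(
        np.random.SeedSequence(entropy=seed, spawn_key=(_STREAMS.index(name),)))


@dataclass(frozen=True)
class SyntheticSpec:
    """Study conditions for the planted-structure generator.

    Defaults are the standard simulation conditions used throughout the
    test substrate: a 30-cell-type tree, 5 planted cell clusters, 8 locus
    clusters of 250 loci, accessible/inaccessible Bernoulli rates 0.8/0.05,
    and half of all loci cell-specific.
    """

    n_cells: int = 30
    k: int = 5
    J: int = 8
    rows_per_cluster: int = 250
    theta_low: float = 0.05
    theta_high: float = 0.8
    frac_cell_specific: float = 0.5
    q_in: float = 0.6
    q_out: float = 0.1
    n_null_motifs: int = 20
    motif_background: float = 0.1
    seed: int = 0

    def __post_init__(self):
        if not 0 <= self.theta_low < self.theta_high <= 1:
            raise ValueError("need 0 <= theta_low < theta_high <= 1")
        if self.k > self.n_cells:
            raise ValueError("k cannot exceed n_cells")
        if min(self.n_cells, self.k, self.J, self.rows_per_cluster) < 1:
            raise ValueError("all counts must be positive")
        if not 0 <= self.q_out < self.q_in <= 1:
            raise ValueError("need 0 <= q_out < q_in <= 1")


@dataclass
class SyntheticDataset:
    spec: SyntheticSpec
    tree: DifferentiationTree
    cutspec: CutSpec
    partition: TreePartition
    col_labels: np.ndarray          # planted cell-cluster id per column
    row_labels: np.ndarray          # planted locus-cluster id per row (-1 = cell-specific)
    states: np.ndarray              # bool (J, k) planted two-state table
    M: np.ndarray                   # binary (n_loci, n_cells)
    A: MotifHitMatrix | None = None

    @property
    def cell_types(self) -> list[str]:
        return self.tree.nodes

    @property
    def locus_names(self) -> list[str]:
        return [f"chrS:{i * 1000}-{i * 1000 + 500}" for i in range(self.M.shape[0])]

    @property
    def clustered_mask(self) -> np.ndarray:
        return self.row_labels >= 0


def random_tree(n_cells: int, seed: int, shape: str = "recursive") -> DifferentiationTree:
    """Random rooted tree over ``n_cells`` named cell types.

    recursive: node i attaches to a uniformly random earlier node (heavy
    branching near the root, as in hematopoiesis); caterpillar: a path;
    balanced: complete binary shape.
    """
    if n_cells < 2:
        raise ValueError("need at least 2 cell types")
    names = [f"ct{i:02d}" for i in range(n_cells)]
    parent: dict[str, str | None] = {names[0]: None}
    if shape == "recursive":
        rng = _substream(seed, "tree")
        for i in range(1, n_cells):
            parent[names[i]] = names[int(rng.integers(i))]
    elif shape == "caterpillar":
        for i in range(1, n_cells):
            parent[names[i]] = names[i - 1]
    elif shape == "balanced":
        for i in range(1, n_cells):
            parent[names[i]] = names[(i - 1) // 2]
    else:
        raise ValueError(f"unknown tree shape {shape!r}")
    return DifferentiationTree(parent)


def random_cutspec(tree: DifferentiationTree, k: int, seed: int,
                   min_width: int | None = None, max_tries: int = 200) -> CutSpec:
    """Random valid cut spec whose induced clusters are not degenerately small.

    Unlike the optimizer's initialiser (whose groups always hold all of a
    vertex's children), each planted cut group is a random nonempty subset
    of the available children, covering the full space of valid cut specs —
    including sibling-subset clusters like those seen in real
    differentiation trees.  Draws with a cluster narrower than ``min_width``
    (default n_cells // (2k), at least 2) are rejected: a planted cluster
    spanning a single cell type is statistically invisible to row
    clustering, so it makes a useless recovery substrate.  Returns the
    widest-minimum draw if no draw satisfies the bound.
    """
    rng = _substream(seed, "partition")
    if min_width is None:
        min_width = max(2, len(tree.nodes) // (2 * k))
    if k == 1:
        return CutSpec(())
    best, best_w = None, -1
    for _ in range(max_tries):
        non_leaves = tree.non_leaves
        order = rng.permutation(len(non_leaves))
        groups: list[tuple[str, frozenset[str]]] = []
        claimed: set[str] = set()
        for idx in order:
            if len(groups) == k - 1:
                break
            v = non_leaves[idx]
            avail = [c for c in tree.children[v] if c not in claimed]
            if not avail:
                continue
            size = int(rng.integers(1, len(avail) + 1))
            members = frozenset(rng.choice(avail, size=size, replace=False))
            groups.append((v, members))
            claimed |= members
        if len(groups) < k - 1:
            continue
        cand = CutSpec(tuple(groups))
        w = min(len(c) for c in partition_from_cutspec(tree, cand).clusters)
        if w >= min_width:
            return cand
        if w > best_w:
            best, best_w = cand, w
    if best is None:
        raise ValueError(f"cannot draw a valid {k}-way cut spec on this tree")
    return best


def simulate_matrix(spec: SyntheticSpec, tree: DifferentiationTree,
                    partition: TreePartition) -> SyntheticDataset:
    """Planted two-state Bernoulli matrix on a known tree partition.

    Each locus cluster draws a state vector over the k cell clusters (at
    least one accessible and, for k > 1, at least one inaccessible); entries
    are Bernoulli(theta_high) in accessible blocks and Bernoulli(theta_low)
    elsewhere; all-zero rows are redrawn; cell-specific rows with 1-2 ones
    are appended.
    """
    k = partition.k
    col_labels = np.asarray(partition.labels(tree.nodes))
    widths = np.array([len(c) for c in partition.clusters], dtype=np.float64)
    rng_states = _substream(spec.seed, "states")
    # Locus clusters are distinguishable only through the columns on which
    # their state vectors differ, so the planted states are chosen as a
    # maximin-separated code (greedy farthest-point in column-weighted
    # Hamming distance) over the valid states: a recovery substrate should
    # sit in the identifiable regime, so that failures to recover indicate
    # implementation errors rather than information limits.
    if k == 1:
        states = np.ones((spec.J, 1), dtype=bool)
    else:
        if k <= 12:
            cand = np.array([[(i >> b) & 1 for b in range(k)]
                             for i in range(1, 2**k - 1)], dtype=bool)
        else:
            cand = np.unique(rng_states.random((1024, k)) < 0.5, axis=0)
            cand = cand[cand.any(axis=1) & ~cand.all(axis=1)]
        states = np.zeros((spec.J, k), dtype=bool)
        states[0] = cand[rng_states.integers(len(cand))]
        for j in range(1, spec.J):
            dists = np.array([
                min(widths[states[i] != c].sum() for i in range(j)) for c in cand])
            best = np.nonzero(dists == dists.max())[0]
            states[j] = cand[best[rng_states.integers(len(best))]]
    rng_e = _substream(spec.seed, "entries")
    n_clustered = spec.J * spec.rows_per_cluster
    rows = []
    row_labels = np.repeat(np.arange(spec.J), spec.rows_per_cluster)
    for j in range(spec.J):
        rates = np.where(states[j][col_labels], spec.theta_high, spec.theta_low)
        block = (rng_e.random((spec.rows_per_cluster, spec.n_cells)) < rates).astype(np.uint8)
        # redraw all-zero rows (a master locus derives from >= 1 peak)
        while True:
            zero = block.sum(axis=1) == 0
            if not zero.any():
                break
            block[zero] = (rng_e.random((int(zero.sum()), spec.n_cells)) < rates).astype(np.uint8)
        rows.append(block)
    M = np.concatenate(rows)
    # appended cell-specific loci: frac_cell_specific of the final total
    f = spec.frac_cell_specific
    n_cs = int(round(n_clustered * f / (1 - f))) if f > 0 else 0
    if n_cs:
        rng_cs = _substream(spec.seed, "cell_specific")
        cs = np.zeros((n_cs, spec.n_cells), dtype=np.uint8)
        counts = rng_cs.integers(1, 3, size=n_cs)
        for i in range(n_cs):
            cols = rng_cs.choice(spec.n_cells, size=counts[i], replace=False)
            cs[i, cols] = 1
        M = np.concatenate([M, cs])
        row_labels = np.concatenate([row_labels, np.full(n_cs, -1)])
    return SyntheticDataset(spec=spec, tree=tree, cutspec=partition.origin,
                            partition=partition, col_labels=col_labels,
                            row_labels=row_labels, states=states, M=M)


def simulate_motifs(dataset: SyntheticDataset, q_in: float | None = None,
                    q_out: float | None = None, target_cocluster: int = 0,
                    seed: int | None = None) -> MotifHitMatrix:
    """Motif matrix with one planted motif and independent null motifs.

    The planted motif is present with probability q_in at the target locus
    cluster's loci and q_out elsewhere; null motifs are i.i.d. Bernoulli at
    the background rate, independent of M.
    """
    spec = dataset.spec
    q_in = spec.q_in if q_in is None else q_in
    q_out = spec.q_out if q_out is None else q_out
    seed = spec.seed if seed is None else seed
    rng = _substream(seed, "motifs")
    L = dataset.M.shape[0]
    target = dataset.row_labels == target_cocluster
    p = np.where(target, q_in, q_out)
    planted = (rng.random(L) < p).astype(np.uint8)
    nulls = (rng.random((L, spec.n_null_motifs)) < spec.motif_background).astype(np.uint8)
    entries = np.column_stack([planted, nulls])
    names = ["planted"] + [f"null{m:02d}" for m in range(spec.n_null_motifs)]
    mat = MotifHitMatrix(dataset.locus_names, names, entries)
    dataset.A = mat
    return mat


def simulate_dataset(spec: SyntheticSpec, with_motifs: bool = False,
                     tree_shape: str = "recursive") -> SyntheticDataset:
    """Tree + planted partition + matrix (+ motifs) from a single seed."""
    tree = random_tree(spec.n_cells, spec.seed, shape=tree_shape)
    cut = random_cutspec(tree, spec.k, spec.seed)
    partition = partition_from_cutspec(tree, cut)
    ds = simulate_matrix(spec, tree, partition)
    if with_motifs:
        simulate_motifs(ds)
    return ds
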