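"""Local-search minimisation of the co-cluster fit over tree-respecting partitions.

The objective is the squared Frobenius distance between the binary matrix M
(restricted to rows in the large locus clusters) and the co-cluster mean
approximation induced by a row clustering together with a column partition
that respects the differentiation tree.  The search moves through cut-spec
space with two move families — cut-group modifications (add / remove /
transfer a child at one cut vertex) and cut-vertex modifications (delete a
cut group at v, open a singleton group at another vertex v') — applied in
fixed cycles until a full double cycle brings no strict improvement, with
random restarts.

For binary M the objective reduces to  sum(M) - sum_coclusters S^2/m  where
S is the entry sum and m the entry count of a co-cluster, so each candidate
is scored from cached per-locus-cluster column sums without rescanning M.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.cluster.hierarchy import fcluster, linkage
from sklearn.cluster import KMeans

from .tree_model import CutSpec, DifferentiationTree, TreePartition, partition_from_cutspec

__all__ = [
    "FitCache",
    "OptimizerRun",
    "cocluster_sse",
    "random_init",
    "cut_group_moves",
    "cut_vertex_moves",
    "optimize",
    "baseline_partition",
]


class FitCache:
    """Per (locus cluster, column) sums of M, for O(J*C*k) objective evaluation."""

    def __init__(self, M_rows: np.ndarray, row_labels: np.ndarray, cell_types: list[str]):
        M = np.asarray(M_rows, dtype=np.float64)
        row_labels = np.asarray(row_labels)
        self.cell_types = list(cell_types)
        self.col_index = {c: i for i, c in enumerate(self.cell_types)}
        self.cluster_ids = np.unique(row_labels)
        self.n_rows = np.array([(row_labels == j).sum() for j in self.cluster_ids])
        self.T = np.stack([M[row_labels == j].sum(axis=0) for j in self.cluster_ids])
        self.total = float(M.sum())

    def sse(self, column_groups: list[np.ndarray]) -> float:
        """SSE of the co-cluster mean model for a column partition (index arrays)."""
        acc = 0.0
        for cols in column_groups:
            S = self.T[:, cols].sum(axis=1)
            m = self.n_rows * len(cols)
            acc += float((S * S / m).sum())
        return self.total - acc

    def sse_partition(self, partition: TreePartition) -> float:
        groups = [np.array([self.col_index[c] for c in cl], dtype=np.intp)
                  for cl in partition.clusters]
        return self.sse(groups)


def cocluster_sse(M_rows: np.ndarray, row_labels: np.ndarray,
                  partition: TreePartition, cell_types: list[str]) -> float:
    """Squared Frobenius distance ||M - M~||^2 for the given co-clustering."""
    return FitCache(M_rows, row_labels, cell_types).sse_partition(partition)


def random_init(tree: DifferentiationTree, k: int, rng: np.random.Generator | int) -> CutSpec:
    """Random initial cut spec: k-1 distinct non-leaf cut vertices, each with
    one cut group holding all of its not-yet-claimed children."""
    if isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(int(rng))
    if k < 1:
        raise ValueError("k must be >= 1")
    if k == 1:
        return CutSpec(())
    non_leaves = tree.non_leaves
    order = list(rng.permutation(len(non_leaves)))
    groups: list[tuple[str, frozenset[str]]] = []
    claimed: set[str] = set()
    for idx in order:
        if len(groups) == k - 1:
            break
        v = non_leaves[idx]
        members = frozenset(c for c in tree.children[v] if c not in claimed)
        if not members:
            continue  # redraw: this vertex's children are exhausted
        groups.append((v, members))
        claimed |= members
    if len(groups) < k - 1:
        raise ValueError(f"cannot draw {k - 1} nonempty cut groups on this tree")
    return CutSpec(tuple(groups))


def _claimed(spec: CutSpec) -> set[str]:
    out: set[str] = set()
    for _, members in spec.groups:
        out |= members
    return out


def cut_group_moves(spec: CutSpec, v: str, tree: DifferentiationTree) -> list[CutSpec]:
    """All cut-group modifications at cut vertex v.

    (a) add one unclaimed child of v to one of v's groups; (b) remove one
    member from a group of size >= 2; (c) transfer a member between two of
    v's groups when the source keeps >= 1 member.  Group count (hence k) is
    conserved.
    """
    vg = [i for i, (p, _) in enumerate(spec.groups) if p == v]
    if not vg:
        raise ValueError(f"{v!r} is not a cut vertex of this spec")
    claimed = _claimed(spec)
    unclaimed = [c for c in tree.children[v] if c not in claimed]
    out: list[CutSpec] = []

    def rebuild(repl: dict[int, frozenset[str]]) -> CutSpec:
        return CutSpec(tuple(
            (p, repl.get(i, m)) for i, (p, m) in enumerate(spec.groups)))

    for gi in vg:
        members = spec.groups[gi][1]
        for c in unclaimed:                      # (a) additions
            out.append(rebuild({gi: members | {c}}))
        if len(members) >= 2:                    # (b) removals
            for r in members:
                out.append(rebuild({gi: members - {r}}))
        if len(vg) > 1:                          # (c) transfers
            for gj in vg:
                if gj == gi or len(members) < 2:
                    continue
                for r in members:
                    out.append(rebuild({gi: members - {r},
                                        gj: spec.groups[gj][1] | {r}}))
    return out


def cut_vertex_moves(spec: CutSpec, v: str, v_prime: str,
                     tree: DifferentiationTree) -> list[CutSpec]:
    """Delete one cut group of v and open a singleton cut group at v_prime.

    The new group's member is any child of v_prime unclaimed after the
    deletion (members freed by the deleted group become available).
    """
    if v_prime == v:
        raise ValueError("v_prime must differ from v")
    vg = [i for i, (p, _) in enumerate(spec.groups) if p == v]
    if not vg:
        raise ValueError(f"{v!r} is not a cut vertex of this spec")
    out: list[CutSpec] = []
    children = tree.children.get(v_prime, [])
    if not children:
        return out
    for gi in vg:
        remaining = tuple(g for i, g in enumerate(spec.groups) if i != gi)
        claimed = set()
        for _, m in remaining:
            claimed |= m
        for c in children:
            if c in claimed:
                continue
            out.append(CutSpec(remaining + ((v_prime, frozenset([c])),)))
    return out


@dataclass
class RestartTrace:
    seed: int
    initial_sse: float
    final_sse: float
    n_moves: int
    n_cycles: int


@dataclass
class OptimizerRun:
    seed: int
    restarts: int
    best_spec: CutSpec
    best_partition: TreePartition
    best_sse: float
    traces: list[RestartTrace]


def _cycle_vertices(spec: CutSpec, tree: DifferentiationTree,
                    rng: np.random.Generator) -> list[str]:
    """Current cut vertices, visited in a per-restart random order.

    The move families are order-sensitive: a fixed visiting order funnels
    every restart into the same few basins, defeating the purpose of the
    random restarts, so each restart draws its own cycle order.
    """
    cut = {p for p, _ in spec.groups}
    order = [v for v in tree.preorder() if v in cut]
    rng.shuffle(order)
    return order


def _local_search(cache: FitCache, tree: DifferentiationTree, spec: CutSpec,
                  rng: np.random.Generator) -> tuple[CutSpec, float, int, int]:
    """Greedy double-cycle descent; returns (spec, sse, n_moves, n_cycles)."""
    cur_sse = cache.sse_partition(partition_from_cutspec(tree, spec))
    n_moves = 0
    n_cycles = 0
    receivers = [v for v in tree.preorder() if tree.children[v]]
    while True:
        n_cycles += 1
        improved = False
        # cycle 1: cut-group modifications, per cut vertex
        for v in _cycle_vertices(spec, tree, rng):
            if v not in {p for p, _ in spec.groups}:
                continue
            best_cand, best_sse = None, cur_sse
            for cand in cut_group_moves(spec, v, tree):
                sse = cache.sse_partition(partition_from_cutspec(tree, cand))
                if sse < best_sse - 1e-12:
                    best_cand, best_sse = cand, sse
            if best_cand is not None:
                spec, cur_sse = best_cand, best_sse
                n_moves += 1
                improved = True
        # cycle 2: cut-vertex modifications, over pairs (v, v')
        for v in _cycle_vertices(spec, tree, rng):
            if v not in {p for p, _ in spec.groups}:
                continue
            rng.shuffle(receivers)
            for v_prime in receivers:
                if v_prime == v:
                    continue
                if v not in {p for p, _ in spec.groups}:
                    break  # v lost its last group to an accepted move
                best_cand, best_sse = None, cur_sse
                for cand in cut_vertex_moves(spec, v, v_prime, tree):
                    sse = cache.sse_partition(partition_from_cutspec(tree, cand))
                    if sse < best_sse - 1e-12:
                        best_cand, best_sse = cand, sse
                if best_cand is not None:
                    spec, cur_sse = best_cand, best_sse
                    n_moves += 1
                    improved = True
        if not improved:
            return spec, cur_sse, n_moves, n_cycles


def optimize(M_rows: np.ndarray, row_labels: np.ndarray, tree: DifferentiationTree,
             k: int, restarts: int = 20, seed: int = 0) -> OptimizerRun:
    """Best tree-respecting k-partition over `restarts` random initialisations.

    Restart t uses seed ``seed + t``; the run is deterministic given seed.
    """
    cache = FitCache(M_rows, row_labels, tree.nodes)
    best_spec, best_sse = None, np.inf
    traces: list[RestartTrace] = []
    for t in range(restarts):
        rseed = (seed + t) % (2**31)
        rng = np.random.default_rng(rseed)
        spec = random_init(tree, k, rng)
        init_sse = cache.sse_partition(partition_from_cutspec(tree, spec))
        spec, sse, n_moves, n_cycles = _local_search(cache, tree, spec, rng)
        traces.append(RestartTrace(rseed, init_sse, sse, n_moves, n_cycles))
        if sse < best_sse:
            best_spec, best_sse = spec, sse
    part = partition_from_cutspec(tree, best_spec)
    return OptimizerRun(seed=seed, restarts=restarts, best_spec=best_spec,
                        best_partition=part, best_sse=best_sse, traces=traces)


def baseline_partition(M_rows: np.ndarray, k: int, method: str = "hierarchical",
                       seed: int = 0, cell_types: list[str] | None = None
                       ) -> list[frozenset[str]] | np.ndarray:
    """Tree-agnostic column clustering baseline.

    hierarchical: Ward linkage on Euclidean distances between columns;
    kmeans: k-means++ with fixed random state.  Returns per-column labels,
    or named clusters when cell_types is given.
    """
    M = np.asarray(M_rows, dtype=np.float64)
    X = M.T  # columns of M as observations
    if k > X.shape[0]:
        raise ValueError("k exceeds number of columns")
    if method == "hierarchical":
        Z = linkage(X, method="ward")
        labels = fcluster(Z, t=k, criterion="maxclust") - 1
    elif method == "kmeans":
        km = KMeans(n_clusters=k, random_state=seed, n_init=10)
        labels = km.fit_predict(X)
    else:
        raise ValueError(f"unknown baseline method {method!r}")
    if cell_types is None:
        return labels
    return [frozenset(np.array(cell_types)[labels == c]) for c in np.unique(labels)]
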