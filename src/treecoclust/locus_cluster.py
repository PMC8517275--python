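"""Locus (row) clustering via a hypergeometric similarity graph and Louvain.

Rows of the binary accessibility matrix are nodes.  For two rows with n and
N ones out of C columns, the number s of columns where both are 1 follows a
hypergeometric null (population C, N successes, n draws) under random
permutation of one row's columns; an upper-tail p-value P(S >= s) scores
their similarity.  Edges are placed at a Benjamini-Hochberg FDR threshold
over all row pairs, and communities are found with the Louvain heuristic.

The O(L^2) pair scan is made tractable by collapsing identical rows into
pattern classes with multiplicities and counting intersections with a
single integer matrix product.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np
from scipy.stats import hypergeom

__all__ = [
    "EdgeTest",
    "SimilarityGraph",
    "LocusClustering",
    "pair_pvalue",
    "edge_threshold",
    "build_graph",
    "louvain_partition",
    "large_clusters",
]

UNCLUSTERED = -1


@dataclass(frozen=True)
class EdgeTest:
    n: int
    N: int
    s: int
    C: int
    p: float


def _check_counts(n: int, N: int, s: int, C: int) -> None:
    if not (0 <= n <= C and 0 <= N <= C):
        raise ValueError(f"row sums n={n}, N={N} must lie in [0, C={C}]")
    if not (max(0, n + N - C) <= s <= min(n, N)):
        raise ValueError(f"s={s} outside hypergeometric support for n={n}, N={N}, C={C}")


def pair_pvalue(n: int, N: int, s: int, C: int) -> float:
    """Upper-tail P(S >= s), S ~ Hypergeom(C, N, n); symmetric in (n, N)."""
    _check_counts(n, N, s, C)
    return float(hypergeom.sf(s - 1, C, N, n))


@dataclass
class _PairTable:
    """All unordered row-pair p-values, collapsed over identical-row classes."""

    pvals: np.ndarray        # per class pair (i <= j)
    weights: np.ndarray      # number of row pairs represented by each entry
    class_of_row: np.ndarray
    n_pairs: int             # total L*(L-1)/2


def _pair_table(M_rows: np.ndarray) -> _PairTable:
    M = np.asarray(M_rows, dtype=np.uint8)
    L, C = M.shape
    if L < 2:
        raise ValueError("need at least 2 rows")
    patterns, inverse, counts = np.unique(M, axis=0, return_inverse=True, return_counts=True)
    P = patterns.astype(np.int64)
    inter = P @ P.T                     # shared-1 counts between classes
    ones = P.sum(axis=1)
    k = len(patterns)
    iu, ju = np.triu_indices(k)
    n_, N_, s_ = ones[iu], ones[ju], inter[iu, ju]
    # weight: cross pairs i<j -> c_i*c_j; within class -> c*(c-1)/2
    w = np.where(iu == ju, counts[iu] * (counts[iu] - 1) // 2, counts[iu] * counts[ju])
    keep = w > 0
    n_, N_, s_, w, iu, ju = n_[keep], N_[keep], s_[keep], w[keep], iu[keep], ju[keep]
    # dedupe hypergeometric evaluations over unique (n, N, s) triples
    trip = np.stack([np.minimum(n_, N_), np.maximum(n_, N_), s_], axis=1)
    uniq, inv = np.unique(trip, axis=0, return_inverse=True)
    pu = hypergeom.sf(uniq[:, 2] - 1, C, uniq[:, 1], uniq[:, 0])
    pv = pu[inv]
    tbl = _PairTable(pvals=pv, weights=w, class_of_row=inverse,
                     n_pairs=L * (L - 1) // 2)
    tbl._iu, tbl._ju = iu, ju  # class-pair indices, used to expand edges
    tbl._classes = patterns
    return tbl


def edge_threshold(M_rows: np.ndarray, fdr: float) -> float:
    """Benjamini-Hochberg p-value cutoff over all unordered row pairs.

    Returns the largest sorted p with p_(i) <= i*fdr/T (T = total pairs), or
    0.0 if no pair passes.
    """
    if not 0 < fdr < 1:
        raise ValueError("fdr must be in (0, 1)")
    tbl = _pair_table(np.asarray(M_rows))
    return _bh_cutoff(tbl.pvals, tbl.weights, tbl.n_pairs, fdr)


def _bh_cutoff(pvals: np.ndarray, weights: np.ndarray, n_tests: int, fdr: float) -> float:
    order = np.argsort(pvals, kind="stable")
    p = pvals[order]
    w = weights[order]
    ranks = np.cumsum(w)  # rank of the *last* pair at or below each p
    ok = p <= ranks * fdr / n_tests
    if not ok.any():
        return 0.0
    return float(p[np.nonzero(ok)[0][-1]])


@dataclass
class SimilarityGraph:
    graph: nx.Graph
    p_cutoff: float
    connected_fraction: float

    @property
    def n_nodes(self) -> int:
        return self.graph.number_of_nodes()

    def write_edges_tsv(self, path) -> None:
        with open(path, "w") as fh:
            for u, v in self.graph.edges():
                fh.write(f"{u}\t{v}\n")


def build_graph(M_rows: np.ndarray, fdr: float) -> SimilarityGraph:
    """Similarity graph: edge (a, b) iff pair p-value <= the BH cutoff."""
    M = np.asarray(M_rows, dtype=np.uint8)
    tbl = _pair_table(M)
    cutoff = _bh_cutoff(tbl.pvals, tbl.weights, tbl.n_pairs, fdr)
    G = nx.Graph()
    G.add_nodes_from(range(M.shape[0]))
    if cutoff > 0:
        sig = tbl.pvals <= cutoff
        rows_of_class = [np.nonzero(tbl.class_of_row == c)[0] for c in range(len(tbl._classes))]
        for ci, cj in zip(tbl._iu[sig], tbl._ju[sig]):
            ri, rj = rows_of_class[ci], rows_of_class[cj]
            if ci == cj:
                for a in range(len(ri)):
                    for b in range(a + 1, len(ri)):
                        G.add_edge(int(ri[a]), int(ri[b]))
            else:
                for a in ri:
                    for b in rj:
                        G.add_edge(int(a), int(b))
    n_conn = sum(1 for v in G.nodes if G.degree(v) >= 1)
    return SimilarityGraph(G, cutoff, n_conn / max(G.number_of_nodes(), 1))


@dataclass
class LocusClustering:
    """Community labels per row; ids are ordered by decreasing cluster size."""

    labels: np.ndarray
    sizes: np.ndarray

    @property
    def n_clusters(self) -> int:
        return len(self.sizes)

    def write_tsv(self, path, locus_names=None) -> None:
        with open(path, "w") as fh:
            for i, lab in enumerate(self.labels):
                name = locus_names[i] if locus_names is not None else str(i)
                fh.write(f"{name}\t{lab}\n")

    @classmethod
    def read_tsv(cls, path):
        labels = []
        with open(path) as fh:
            for line in fh:
                labels.append(int(line.rstrip("\n").split("\t")[1]))
        labels = np.asarray(labels)
        sizes = np.bincount(labels)
        return cls(labels=labels, sizes=sizes)


def louvain_partition(graph: SimilarityGraph, resolution: float = 1.0,
                      seed: int = 0) -> LocusClustering:
    """Louvain communities of the similarity graph; deterministic given seed.

    Isolated nodes come out as singleton clusters.  Cluster ids are
    relabelled 0, 1, ... by decreasing size, ties by smallest member row.
    """
    G = graph.graph
    if G.number_of_nodes() == 0:
        raise ValueError("graph is empty")
    comms = nx.community.louvain_communities(G, resolution=resolution, seed=seed)
    comms = sorted(comms, key=lambda c: (-len(c), min(c)))
    labels = np.empty(G.number_of_nodes(), dtype=np.int64)
    for cid, members in enumerate(comms):
        for v in members:
            labels[v] = cid
    return LocusClustering(labels=labels, sizes=np.array([len(c) for c in comms]))


def large_clusters(clustering: LocusClustering, min_size: int = 30) -> list[int]:
    """Cluster ids with size >= min_size, by decreasing size then first row."""
    return [cid for cid in range(clustering.n_clusters)
            if clustering.sizes[cid] >= min_size]
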