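"""Rooted differentiation trees and tree-respecting cell-type partitions.

A differentiation tree is a rooted tree whose nodes are cell types (the
columns of the accessibility matrix) and whose edges are parent -> child
differentiation steps.  A set of cell types *respects* the tree if it is
connected in the undirected tree, or if the roots of its connected
components are all children of one common parent node.  k-way partitions of
the cell types into tree-respecting blocks are encoded by a :class:`CutSpec`:
k-1 cut groups, each a cut vertex ``p`` together with a nonempty subset of
its children whose edges to ``p`` are severed.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

__all__ = [
    "DifferentiationTree",
    "CutSpec",
    "TreePartition",
    "respects_tree",
    "partition_from_cutspec",
    "decompose_connected",
    "decompose_respecting",
]


class DifferentiationTree:
    """Rooted tree over cell-type names.

    Parameters
    ----------
    parent
        Mapping node -> parent name; exactly one node (the root) maps to
        ``None``.  Node order is the insertion order of the mapping and is
        the canonical column order used elsewhere.
    """

    def __init__(self, parent: dict[str, str | None]):
        roots = [n for n, p in parent.items() if p is None]
        if len(roots) != 1:
            raise ValueError(f"tree must have exactly one root, found {len(roots)}")
        self.root: str = roots[0]
        self.parent: dict[str, str | None] = dict(parent)
        self.nodes: list[str] = list(parent)
        self.children: dict[str, list[str]] = {n: [] for n in self.nodes}
        for n, p in parent.items():
            if p is None:
                continue
            if p not in self.children:
                raise ValueError(f"parent {p!r} of {n!r} is not a node")
            self.children[p].append(n)
        # depth via BFS; also detects cycles/disconnected parts
        self.depth: dict[str, int] = {self.root: 0}
        queue = [self.root]
        while queue:
            nxt = []
            for u in queue:
                for c in self.children[u]:
                    self.depth[c] = self.depth[u] + 1
                    nxt.append(c)
            queue = nxt
        if len(self.depth) != len(self.nodes):
            raise ValueError("parent map contains a cycle or unreachable nodes")

    # -- basic queries -------------------------------------------------
    def __len__(self) -> int:
        return len(self.nodes)

    def is_leaf(self, node: str) -> bool:
        return not self.children[node]

    @property
    def non_leaves(self) -> list[str]:
        return [n for n in self.nodes if self.children[n]]

    def preorder(self) -> list[str]:
        out: list[str] = []
        stack = [self.root]
        while stack:
            u = stack.pop()
            out.append(u)
            stack.extend(reversed(self.children[u]))
        return out

    # -- io ------------------------------------------------------------
    @classmethod
    def from_edges(cls, edges: Iterable[tuple[str, str]]) -> "DifferentiationTree":
        """Build from (child, parent) pairs; parent '-' marks the root."""
        parent: dict[str, str | None] = {}
        for child, par in edges:
            parent[child] = None if par == "-" else par
        return cls(parent)

    @classmethod
    def read_tsv(cls, path) -> "DifferentiationTree":
        """Read a two-column TSV (child, parent), root's parent written '-'."""
        edges = []
        with open(path) as fh:
            for ln, line in enumerate(fh, 1):
                line = line.rstrip("\n")
                if not line or line.startswith("#"):
                    continue
                parts = line.split("\t")
                if len(parts) != 2:
                    raise ValueError(f"{path}:{ln}: expected 2 columns, got {len(parts)}")
                edges.append((parts[0], parts[1]))
        return cls.from_edges(edges)

    def write_tsv(self, path) -> None:
        with open(path, "w") as fh:
            for n in self.nodes:
                fh.write(f"{n}\t{self.parent[n] or '-'}\n")


@dataclass(frozen=True)
class CutSpec:
    """Cut-group encoding of a k-way tree-respecting partition.

    ``groups`` is a tuple of ``(cut_vertex, members)`` pairs; each member is
    a child of its group's cut vertex and members are globally unique across
    groups.  Cut vertices may repeat across groups.  ``k`` = len(groups)+1.
    """

    groups: tuple[tuple[str, frozenset[str]], ...]

    @property
    def k(self) -> int:
        return len(self.groups) + 1

    @property
    def cut_vertices(self) -> list[str]:
        seen: list[str] = []
        for p, _ in self.groups:
            if p not in seen:
                seen.append(p)
        return seen

    def validate(self, tree: DifferentiationTree) -> None:
        claimed: set[str] = set()
        for p, members in self.groups:
            if not members:
                raise ValueError(f"empty cut group at vertex {p!r}")
            for r in members:
                if tree.parent.get(r) != p:
                    raise ValueError(f"member {r!r} is not a child of cut vertex {p!r}")
                if r in claimed:
                    raise ValueError(f"member {r!r} appears in more than one cut group")
                claimed.add(r)

    @staticmethod
    def make(groups: Sequence[tuple[str, Iterable[str]]]) -> "CutSpec":
        return CutSpec(tuple((p, frozenset(m)) for p, m in groups))


@dataclass
class TreePartition:
    """Disjoint cover of the tree's nodes; every block respects the tree.

    The last cluster is the one containing the tree root when built from a
    CutSpec.
    """

    clusters: list[frozenset[str]]
    origin: CutSpec | None = None

    @property
    def k(self) -> int:
        return len(self.clusters)

    def labels(self, order: Sequence[str]) -> list[int]:
        """Cluster id per node, in the given (column) order."""
        lab = {}
        for i, cl in enumerate(self.clusters):
            for n in cl:
                lab[n] = i
        return [lab[n] for n in order]

    def as_key(self) -> frozenset[frozenset[str]]:
        """Order-insensitive identity, for comparing partitions."""
        return frozenset(self.clusters)


def _component_roots(node_set: Iterable[str], tree: DifferentiationTree) -> list[str]:
    """Roots (shallowest nodes) of the connected components induced by the set."""
    s = set(node_set)
    if not s:
        raise ValueError("node set must be nonempty")
    for n in s:
        if n not in tree.parent:
            raise ValueError(f"node {n!r} not in tree")
    # a node roots its component iff its parent is outside the set
    return [n for n in s if tree.parent[n] not in s]


def respects_tree(node_set: Iterable[str], tree: DifferentiationTree) -> bool:
    """True iff the set is connected or all component roots share one parent."""
    roots = _component_roots(node_set, tree)
    if len(roots) == 1:
        return True
    parents = {tree.parent[r] for r in roots}
    # the tree root's component has parent None, which can never be shared
    return len(parents) == 1 and None not in parents


def decompose_connected(node_set: Iterable[str], tree: DifferentiationTree) -> int:
    """Number of connected components of the induced subgraph."""
    return len(_component_roots(node_set, tree))


def decompose_respecting(node_set: Iterable[str], tree: DifferentiationTree) -> int:
    """Minimal number of tree-respecting components covering the set.

    Connected components are grouped by the parent of their roots; the
    component containing the tree root (parent ``None``) always stands
    alone.
    """
    roots = _component_roots(node_set, tree)
    return len({tree.parent[r] for r in roots})


def partition_from_cutspec(tree: DifferentiationTree, spec: CutSpec) -> TreePartition:
    """Sever each (cut vertex, member) edge and collect the pieces.

    Cluster i is the union of subtrees rooted at group i's members; the
    final cluster is the piece containing the tree root.
    """
    spec.validate(tree)
    severed: dict[str, int] = {}  # member -> group index
    for gi, (_, members) in enumerate(spec.groups):
        for r in members:
            severed[r] = gi
    # climb from every node to the root of its post-cut component
    comp: dict[str, int] = {}  # node -> cluster index (len(groups) = root cluster)
    root_cluster = len(spec.groups)
    for n in tree.nodes:
        path = []
        u = n
        while True:
            if u in comp:
                label = comp[u]
                break
            if u in severed:
                label = severed[u]
                break
            if tree.parent[u] is None:
                label = root_cluster
                break
            path.append(u)
            u = tree.parent[u]
        comp[u] = label
        for v in path:
            comp[v] = label
    clusters = [set() for _ in range(root_cluster + 1)]
    for n, ci in comp.items():
        clusters[ci].add(n)
    return TreePartition([frozenset(c) for c in clusters], origin=spec)
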