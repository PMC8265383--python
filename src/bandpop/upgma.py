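"""UPGMA dendrogram construction, Newick output and cluster purity.

Classical (unweighted, i.e. size-proportional averaging) UPGMA: the
closest pair of clusters merges at height d/2; the distance from the
merged cluster to any other is the member-count-weighted average of its
parts' distances.  The resulting rooted tree is ultrametric — every leaf
sits at the same distance from the root, and the cophenetic distance
between two leaves is twice the height of their lowest common ancestor.

When several pairs tie at the minimum distance (common on binary data)
the pair with the lexicographically smallest (cluster-id, cluster-id)
tuple merges first, where a cluster's id is its smallest member label;
topology is therefore deterministic across runs and platforms.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .distance import DistanceMatrix
from .matrix import PopulationLayout

__all__ = ["UpgmaNode", "UpgmaTree", "upgma", "total_branch_length",
           "to_newick", "leaf_group_purity", "GroupPurity"]

_TIE_TOL = 1e-12


@dataclass
class UpgmaNode:
    """Node of an UPGMA tree; leaves carry a name, internal nodes children."""

    height: float
    name: str | None = None
    children: list["UpgmaNode"] = field(default_factory=list)
    length: float = 0.0          # branch to parent; 0 at the root

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def leaves(self) -> list["UpgmaNode"]:
        if self.is_leaf:
            return [self]
        out = []
        for c in self.children:
            out.extend(c.leaves())
        return out


@dataclass
class UpgmaTree:
    """Rooted ultrametric binary tree over accession leaves."""

    root: UpgmaNode
    leaf_labels: tuple[str, ...]
    # merge log: (left leafset, right leafset, height), in merge order
    merges: list[tuple[frozenset, frozenset, float]] = field(
        default_factory=list)

    @property
    def height(self) -> float:
        return self.root.height

    def nodes(self) -> list[UpgmaNode]:
        out, stack = [], [self.root]
        while stack:
            node = stack.pop()
            out.append(node)
            stack.extend(node.children)
        return out

    def cophenetic_matrix(self) -> np.ndarray:
        """Cophenetic distances (2 x LCA height) ordered as leaf_labels."""
        pos = {l: i for i, l in enumerate(self.leaf_labels)}
        n = len(self.leaf_labels)
        out = np.zeros((n, n))

        def visit(node: UpgmaNode):
            if node.is_leaf:
                return [node.name]
            sets = [visit(c) for c in node.children]
            for a in range(len(sets)):
                for b in range(a + 1, len(sets)):
                    for la in sets[a]:
                        for lb in sets[b]:
                            d = 2.0 * node.height
                            out[pos[la], pos[lb]] = d
                            out[pos[lb], pos[la]] = d
            return [l for s in sets for l in s]

        visit(self.root)
        return out

    def cut(self, k: int) -> dict[str, int]:
        """Membership after cutting into *k* clusters (undo last k-1 merges)."""
        n = len(self.leaf_labels)
        if not 1 <= k <= n:
            raise ValueError(f"k must be in [1, {n}], got {k}")
        cluster_of = {l: i for i, l in enumerate(self.leaf_labels)}
        for left, right, _h in self.merges[:n - k]:
            target = min(cluster_of[l] for l in left | right)
            for l in left | right:
                cluster_of[l] = target
        relabel = {c: i for i, c in
                   enumerate(dict.fromkeys(cluster_of.values()))}
        return {l: relabel[c] for l, c in cluster_of.items()}


def upgma(dist: DistanceMatrix) -> UpgmaTree:
    """Build the UPGMA tree of *dist* (n >= 2)."""
    n = dist.n
    if n < 2:
        raise ValueError(f"UPGMA needs at least 2 leaves, got {n}")
    labels = list(dist.labels)
    nodes = [UpgmaNode(height=0.0, name=l) for l in labels]
    ids = [l for l in labels]                 # cluster id = smallest member
    members = [frozenset([l]) for l in labels]
    sizes = [1] * n
    d = dist.values.astype(float).copy()
    active = list(range(n))
    merges: list[tuple[frozenset, frozenset, float]] = []

    while len(active) > 1:
        # find minimum, break ties by lexicographic (id, id)
        best = None
        for ai in range(len(active)):
            for bi in range(ai + 1, len(active)):
                i, j = active[ai], active[bi]
                dij = d[i, j]
                key = tuple(sorted((ids[i], ids[j])))
                if best is None or dij < best[0] - _TIE_TOL or (
                        abs(dij - best[0]) <= _TIE_TOL and key < best[1]):
                    best = (dij, key, i, j)
        dmin, _key, i, j = best
        height = dmin / 2.0
        for c in (nodes[i], nodes[j]):
            c.length = height - c.height
        parent = UpgmaNode(height=height, children=[nodes[i], nodes[j]])
        merges.append((members[i], members[j], height))
        # weighted (size-proportional) average to every other cluster
        for x in active:
            if x in (i, j):
                continue
            dx = (sizes[i] * d[i, x] + sizes[j] * d[j, x]) / (sizes[i] + sizes[j])
            d[i, x] = d[x, i] = dx
        nodes[i] = parent
        members[i] = members[i] | members[j]
        sizes[i] = sizes[i] + sizes[j]
        ids[i] = min(ids[i], ids[j])
        active.remove(j)

    root = nodes[active[0]]
    return UpgmaTree(root=root, leaf_labels=tuple(labels), merges=merges)


def total_branch_length(tree: UpgmaTree) -> float:
    """Sum of all branch lengths of *tree*."""
    return float(sum(node.length for node in tree.nodes()))


def _quote_label(label: str) -> str:
    if any(c in label for c in "()[]:;, \t'\""):
        return "'" + label.replace("'", "''") + "'"
    return label


def to_newick(tree: UpgmaTree, precision: int = 10) -> str:
    """Serialize *tree* as a Newick string with branch lengths."""

    def fmt(x: float) -> str:
        return f"{x:.{precision}g}"

    def render(node: UpgmaNode) -> str:
        if node.is_leaf:
            return f"{_quote_label(node.name)}:{fmt(node.length)}"
        inner = ",".join(render(c) for c in node.children)
        return f"({inner}):{fmt(node.length)}"

    if tree.root.is_leaf:
        return f"{_quote_label(tree.root.name)};"
    inner = ",".join(render(c) for c in tree.root.children)
    return f"({inner});"


@dataclass
class GroupPurity:
    """How well a k-cluster cut of the tree recovers the populations.

    ``per_population`` holds, for each population, the largest fraction of
    its members falling in a single cluster (1.0 = intact).  ``overall``
    is the fraction of populations whose members form a single cluster.
    """

    k: int
    per_population: dict[str, float]
    overall: float


def leaf_group_purity(tree: UpgmaTree,
                      layout: PopulationLayout | dict[str, str],
                      k_clusters: int) -> GroupPurity:
    """Purity of populations under the k-cluster cut of *tree*."""
    cluster_of = tree.cut(k_clusters)
    if isinstance(layout, PopulationLayout):
        pop_of = {}
        pos = 0
        for p, s in zip(layout.populations, layout.sizes):
            for l in tree.leaf_labels[pos:pos + s]:
                pop_of[l] = p
            pos += s
    else:
        pop_of = dict(layout)
    by_pop: dict[str, list[int]] = {}
    for leaf in tree.leaf_labels:
        by_pop.setdefault(pop_of[leaf], []).append(cluster_of[leaf])
    per_pop = {}
    intact = 0
    for p, clusters in by_pop.items():
        counts = np.bincount(clusters)
        share = counts.max() / len(clusters)
        per_pop[p] = float(share)
        if share == 1.0:
            intact += 1
    return GroupPurity(k=k_clusters, per_population=per_pop,
                       overall=intact / len(by_pop))
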