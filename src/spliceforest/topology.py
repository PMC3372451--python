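"""Transcript-forest topologies: skeletons of transcript trees on a gene tree.

A *topology* is a forest of transcript trees with leaves not yet assigned.
Every transcript tree is a subtree of the gene tree and visits each gene at
most once, so a tree is fully described by its root gene and the set of leaf
genes it reaches: its node set is the union of the gene-tree paths from the
root to those leaves.  A tree node at an internal gene with a missing child
is a transcript death on that edge; a parentless tree root is a transcript
birth.  Transcript-tree nodes at internal genes always retain at least one
child (a slot dying on both edges adds cost without explanatory power and is
excluded), so transcript-tree leaves always sit at gene-tree leaves.

The number of trees covering a leaf gene must equal the number of observed
transcripts of that gene; slots of ancestral genes are whatever the trees
induce.  Slots within a gene are interchangeable, which makes the sorted
multiset of (root, leaf set) pairs a canonical key.
"""

from __future__ import annotations

import itertools
import json
import math
from dataclasses import dataclass
from functools import cached_property

from .model import GeneTree

__all__ = [
    "TreeShape",
    "Topology",
    "GuideTree",
    "remove_edge",
    "branch_swap",
    "is_valid",
    "canonical_key",
    "enumerate_topologies",
    "build_guide_tree",
    "all_tree_shapes",
]


@dataclass(frozen=True, order=True)
class TreeShape:
    """One transcript tree: root gene plus the leaf genes it reaches."""

    root: str
    leaves: tuple[str, ...]

    def __post_init__(self):
        object.__setattr__(self, "leaves", tuple(sorted(set(self.leaves))))
        if not self.leaves:
            raise ValueError("a transcript tree must reach at least one leaf gene")

    @property
    def leafset(self) -> frozenset[str]:
        return frozenset(self.leaves)


def shape_span(tree: GeneTree, shape: TreeShape) -> frozenset[str]:
    """Gene nodes visited by the tree (paths root→each leaf)."""
    span: set[str] = set()
    for leaf in shape.leaves:
        path = []
        node = leaf
        while node is not None:
            path.append(node)
            if node == shape.root:
                break
            node = tree.parent(node)
        else:
            raise ValueError(
                f"leaf gene {leaf!r} is not below shape root {shape.root!r}"
            )
        span.update(path)
    return frozenset(span)


def shape_deaths(tree: GeneTree, shape: TreeShape) -> int:
    """Transcript deaths implied by the shape (missing children at internal genes)."""
    span = shape_span(tree, shape)
    return sum(
        sum(1 for c in tree.children(n) if c not in span)
        for n in span
        if not tree.is_leaf(n)
    )


class Topology:
    """A forest of :class:`TreeShape` on one gene tree (leaves unassigned)."""

    def __init__(self, gene_tree: GeneTree, trees):
        self.gene_tree = gene_tree
        self.trees: tuple[TreeShape, ...] = tuple(sorted(trees))
        if not self.trees:
            raise ValueError("a topology needs at least one tree")
        self.spans: tuple[frozenset[str], ...] = tuple(
            shape_span(gene_tree, s) for s in self.trees
        )

    @property
    def n_tree(self) -> int:
        return len(self.trees)

    @cached_property
    def n_death(self) -> int:
        return sum(shape_deaths(self.gene_tree, s) for s in self.trees)

    @cached_property
    def canonical_key(self) -> tuple:
        return tuple((s.root, s.leaves) for s in self.trees)

    def slots(self, gene: str) -> tuple[int, ...]:
        """Indices of trees hosting a slot at ``gene`` (deterministic order)."""
        return tuple(i for i, sp in enumerate(self.spans) if gene in sp)

    def leaf_counts(self) -> dict[str, int]:
        return {
            g: sum(1 for s in self.trees if g in s.leafset)
            for g in self.gene_tree.leaves
        }

    def spanned_edges(self) -> frozenset[tuple[str, str]]:
        out = set()
        for sp in self.spans:
            for n in sp:
                for c in self.gene_tree.children(n):
                    if c in sp:
                        out.add((n, c))
        return frozenset(out)

    def box_key(self, tree_index: int, gene: str) -> tuple[str, ...]:
        """Subtree-shape key of a slot at ``gene``: its leaf genes below ``gene``."""
        return tuple(
            sorted(self.trees[tree_index].leafset & self.gene_tree.leaf_set(gene))
        )

    def __eq__(self, other):
        return isinstance(other, Topology) and self.canonical_key == other.canonical_key

    def __hash__(self):
        return hash(self.canonical_key)

    def __repr__(self):
        trees = ", ".join(
            f"{s.root}({','.join(s.leaves)})" for s in self.trees
        )
        return f"Topology[{trees}]"

    def to_json(self) -> str:
        return json.dumps(
            {"trees": [{"root": s.root, "leaves": list(s.leaves)} for s in self.trees]}
        )


def canonical_key(topo: Topology) -> tuple:
    """Hashable key equal for topologies that differ only by slot permutations."""
    return topo.canonical_key


def is_valid(topo: Topology) -> bool:
    """Every gene hosts a slot and the spanned-edge gene graph is connected."""
    covered = set().union(*topo.spans)
    tree = topo.gene_tree
    if covered != set(tree.postorder()):
        return False
    adj: dict[str, set[str]] = {n: set() for n in tree.postorder()}
    for p, c in topo.spanned_edges():
        adj[p].add(c)
        adj[c].add(p)
    start = tree.root
    seen = {start}
    stack = [start]
    while stack:
        for nb in adj[stack.pop()]:
            if nb not in seen:
                seen.add(nb)
                stack.append(nb)
    return len(seen) == len(adj)


def remove_edge(topo: Topology, tree_index: int, child_gene: str) -> Topology:
    """Cut the link entering ``child_gene`` in one tree: the subtree below
    becomes a new tree (a birth) and the remnant gains a death on that side."""
    tree = topo.gene_tree
    shape = topo.trees[tree_index]
    span = topo.spans[tree_index]
    parent = tree.parent(child_gene)
    if child_gene not in span or parent is None or parent not in span or \
            shape.root == child_gene:
        raise ValueError(
            f"tree {tree_index} has no link into gene {child_gene!r}"
        )
    below = shape.leafset & tree.leaf_set(child_gene)
    rest = shape.leafset - below
    if not rest:
        raise ValueError(
            "removal would leave a childless slot at an internal gene"
        )
    trees = list(topo.trees)
    trees[tree_index] = TreeShape(shape.root, tuple(rest))
    trees.append(TreeShape(child_gene, tuple(below)))
    return Topology(tree, trees)


def branch_swap(
    topo: Topology, link1: tuple[int, str], link2: tuple[int, str]
) -> Topology:
    """Exchange the subtrees hanging below the same gene-tree edge in two trees."""
    (i1, c1), (i2, c2) = link1, link2
    if c1 != c2:
        raise ValueError("branch swap requires slots of the same gene")
    tree = topo.gene_tree
    parent = tree.parent(c1)
    for i in (i1, i2):
        sp = topo.spans[i]
        if c1 not in sp or parent is None or parent not in sp or \
                topo.trees[i].root == c1:
            raise ValueError(f"tree {i} has no link into gene {c1!r}")
    if i1 == i2:
        return topo
    below = tree.leaf_set(c1)
    s1, s2 = topo.trees[i1], topo.trees[i2]
    s1_below, s2_below = s1.leafset & below, s2.leafset & below
    trees = list(topo.trees)
    trees[i1] = TreeShape(s1.root, tuple((s1.leafset - s1_below) | s2_below))
    trees[i2] = TreeShape(s2.root, tuple((s2.leafset - s2_below) | s1_below))
    return Topology(tree, trees)


def all_tree_shapes(tree: GeneTree) -> list[TreeShape]:
    """Every possible transcript-tree shape on the gene tree, sorted."""
    shapes = []
    for r in tree.postorder():
        leaves = sorted(tree.leaf_set(r))
        for k in range(1, len(leaves) + 1):
            for combo in itertools.combinations(leaves, k):
                shapes.append(TreeShape(r, combo))
    return sorted(shapes)


def _level_topologies(
    tree: GeneTree,
    leaf_counts: dict[str, int],
    n_trees: int,
    death_budget: float | None,
    shape_costs: dict[TreeShape, float] | None = None,
    cost_budget: float | None = None,
) -> list[Topology]:
    """All coverage-exact ``n_trees``-tree forests (validity not yet filtered).

    ``shape_costs`` optionally assigns every shape a non-negative lower bound
    on its contribution to any solution score; forests whose summed bound
    exceeds ``cost_budget`` are pruned during construction.
    """
    shapes = all_tree_shapes(tree)
    deaths = [shape_deaths(tree, s) for s in shapes]
    leaf_order = list(tree.leaves)
    covering: dict[str, list[int]] = {l: [] for l in leaf_order}
    for j, s in enumerate(shapes):
        for l in s.leaves:
            covering[l].append(j)
    budget = math.inf if death_budget is None else death_budget
    cbudget = math.inf if cost_budget is None else cost_budget
    cost = (
        [shape_costs[s] for s in shapes] if shape_costs is not None
        else [0.0] * len(shapes)
    )
    # suffix minima let partial forests account for their unchosen trees
    suffix_min = [0.0] * (len(shapes) + 1)
    suffix_min[-1] = math.inf
    for j in range(len(shapes) - 1, -1, -1):
        suffix_min[j] = min(cost[j], suffix_min[j + 1])
    out: list[Topology] = []
    demand = dict(leaf_counts)
    chosen: list[int] = []

    def rec(start: int, left: int, deaths_used: int, cost_used: float) -> None:
        total = sum(demand.values())
        if left == 0:
            if total == 0:
                out.append(Topology(tree, [shapes[j] for j in chosen]))
            return
        if total < left:
            return
        first = next((l for l in leaf_order if demand[l] > 0), None)
        if first is None:
            return
        if not covering[first] or covering[first][-1] < start:
            return
        if cost_used + left * suffix_min[start] > cbudget:
            return
        for j in range(start, len(shapes)):
            s = shapes[j]
            if deaths_used + deaths[j] > budget:
                continue
            nc = cost_used + cost[j]
            if nc + (left - 1) * suffix_min[j] > cbudget:
                continue
            if any(demand[l] == 0 for l in s.leaves):
                continue
            for l in s.leaves:
                demand[l] -= 1
            chosen.append(j)
            rec(j, left - 1, deaths_used + deaths[j], nc)
            chosen.pop()
            for l in s.leaves:
                demand[l] += 1

    rec(0, n_trees, 0, 0.0)
    return out


def enumerate_topologies(
    tree: GeneTree,
    leaf_counts: dict[str, int],
    max_trees: int | None = None,
    *,
    death_budget: float | None = None,
    include_invalid: bool = False,
):
    """Yield unique valid topologies with increasing numbers of trees.

    Within one tree count topologies come in canonical-key order, so runs are
    reproducible.  ``death_budget`` optionally prunes forests whose implied
    death count alone exceeds the budget (used by the search).  The smallest
    feasible tree count is the largest per-leaf transcript count; the largest
    is the total transcript count (every tree covers at least one leaf slot).
    """
    if any(v < 1 for v in leaf_counts.values()):
        raise ValueError("every leaf gene needs at least one transcript")
    missing = set(tree.leaves) - set(leaf_counts)
    if missing:
        raise ValueError(f"leaf_counts missing genes: {sorted(missing)}")
    t_min = max(leaf_counts.values())
    t_max = sum(leaf_counts.values())
    if max_trees is not None:
        t_max = min(t_max, max_trees)
    for t in range(t_min, t_max + 1):
        level = _level_topologies(tree, leaf_counts, t, death_budget)
        level.sort(key=lambda tp: tp.canonical_key)
        for tp in level:
            if include_invalid or is_valid(tp):
                yield tp


@dataclass(frozen=True)
class GuideTree:
    """Per gene, transcript slots grouped into boxes of identical subtree shape.

    ``boxes[gene]`` maps a box key (the leaf genes the subtree reaches below
    ``gene``) to its dot count, i.e. the number of slots with that shape.
    """

    boxes: dict[str, dict[tuple[str, ...], int]]

    def slot_count(self, gene: str) -> int:
        return sum(self.boxes.get(gene, {}).values())


def build_guide_tree(topo: Topology) -> GuideTree:
    boxes: dict[str, dict[tuple[str, ...], int]] = {}
    for gene in topo.gene_tree.postorder():
        per: dict[tuple[str, ...], int] = {}
        for i in topo.slots(gene):
            key = topo.box_key(i, gene)
            per[key] = per.get(key, 0) + 1
        if per:
            boxes[gene] = per
    return GuideTree(boxes)
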