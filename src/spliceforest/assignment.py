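"""Leaf assignment: map observed transcripts onto a topology's leaf slots.

Given a topology, the observed transcripts of each leaf gene must be matched
to that gene's transcript slots, and ancestral transcript vectors inferred, so
that the sum of the maximum-parsimony scores of the transcript trees (S_F) is
minimal.  A *state* of a gene is an ordered list of its slots with pointers
into one state of each child; the guide tree restricts pointers to child slots
of the matching subtree shape.  States are scored bottom-up: the score of a
state includes, for each slot that is a tree root under the parent's choice,
the Sankoff parsimony score minMP of that tree, with exon profiles combined
per column.

Transcript-level exon changes cost ``c_E`` per column, except on an edge where
the gene gained the exon as constitutive or lost it — those changes are free.
A column absent from a gene admits only the excluded configuration there.

The procedure is exhaustive for gene trees of depth two or less (deeper
choices are committed one level below the node where their profiles are
consumed), and a heuristic above that; all co-optimal assignments found by
backtracking are re-scored exactly on the assembled forests.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass, field

import numpy as np

from .ancestral import GeneEvent, free_columns, gene_level_events
from .model import Costs, ExonColumn, ExonState, ExonStateMatrix, GeneTree, Transcript
from .topology import GuideTree, Topology, TreeShape, shape_span

logger = logging.getLogger("spliceforest")

__all__ = [
    "count_states",
    "State",
    "enumerate_states",
    "exon_profile",
    "observed_profile",
    "minMP",
    "assign_leaves",
    "AssignmentResult",
    "ForestAssignment",
    "AssignedTree",
    "ScoringContext",
]


def count_states(n: int, k_lr: int, k_l: int, k_r: int) -> int:
    """Unconstrained upper bound on the number of states at a gene.

    ``n`` is the slot count of each child state, ``k_lr`` the number of slots
    with two children, ``k_l``/``k_r`` those with only a left/right child:
    C(n, k_LR) * n!/(n-k_LR)! * C(n-k_LR, k_L) * C(n-k_LR, k_R).
    """
    if min(n, k_lr, k_l, k_r) < 0:
        raise ValueError("state-count arguments must be non-negative")
    if k_lr + k_l > n or k_lr + k_r > n:
        raise ValueError("more pointered slots than child slots")
    return (
        math.comb(n, k_lr)
        * math.perm(n, k_lr)
        * math.comb(n - k_lr, k_l)
        * math.comb(n - k_lr, k_r)
    )


@dataclass(frozen=True)
class State:
    """Pointer pattern of one gene: per slot, the child-slot it connects to.

    For internal genes ``left``/``right`` hold, per slot, an index into the
    child gene's slot list or None.  For leaf genes ``order`` maps slot index
    to observed-transcript index.
    """

    gene: str
    left: tuple | None = None
    right: tuple | None = None
    order: tuple | None = None


def _injections(need_keys: list, child_keys: list) -> list[tuple]:
    """All shape-respecting injective pointer patterns for one side.

    ``need_keys[i]`` is the required subtree-shape key of slot ``i`` (None if
    the slot has no child on this side); ``child_keys[j]`` the shape key of
    child slot ``j``.  Within a shape class any injection is allowed.
    """
    by_need: dict = {}
    for i, k in enumerate(need_keys):
        if k is not None:
            by_need.setdefault(k, []).append(i)
    by_child: dict = {}
    for j, k in enumerate(child_keys):
        by_child.setdefault(k, []).append(j)
    class_opts = []
    for k, positions in sorted(by_need.items()):
        avail = by_child.get(k, [])
        if len(avail) < len(positions):
            return []
        class_opts.append(
            [(positions, perm) for perm in itertools.permutations(avail, len(positions))]
        )
    out = []
    for combo in itertools.product(*class_opts):
        ptr: list = [None] * len(need_keys)
        for positions, perm in combo:
            for i, j in zip(positions, perm):
                ptr[i] = j
        out.append(tuple(ptr))
    return out


def _slot_need_keys(topo: Topology, gene: str, child: str) -> list:
    keys = []
    for i in topo.slots(gene):
        if child in topo.spans[i]:
            keys.append(topo.box_key(i, child))
        else:
            keys.append(None)
    return keys


def enumerate_states(
    gene: str,
    topo: Topology,
    guide: GuideTree,
    left_state: State | None = None,
    right_state: State | None = None,
) -> list[State]:
    """All guide-tree-compatible states of ``gene`` given one state per child.

    For a leaf gene the states are the k! assignments of observed transcripts
    to its k slots (all slots share the single leaf box).  The returned list
    never exceeds the :func:`count_states` bound for the gene's slot pattern.
    """
    tree = topo.gene_tree
    if tree.is_leaf(gene):
        k = len(topo.slots(gene))
        return [State(gene, order=perm) for perm in itertools.permutations(range(k))]
    cl, cr = tree.children(gene)
    for st, child in ((left_state, cl), (right_state, cr)):
        if st is not None and st.gene != child:
            raise ValueError(f"state of gene {st.gene!r} is not a child of {gene!r}")
    lefts = _injections(
        _slot_need_keys(topo, gene, cl), [topo.box_key(j, cl) for j in topo.slots(cl)]
    )
    rights = _injections(
        _slot_need_keys(topo, gene, cr), [topo.box_key(j, cr) for j in topo.slots(cr)]
    )
    return [State(gene, left=l, right=r) for l in lefts for r in rights]


# ---------------------------------------------------------------------------
# numeric scoring machinery
# ---------------------------------------------------------------------------


class ScoringContext:
    """Precomputed masks and per-edge free columns for one instance."""

    def __init__(
        self,
        tree: GeneTree,
        transcripts: dict[str, list[Transcript]],
        columns: list[ExonColumn],
        ancestral: ExonStateMatrix,
        costs: Costs,
        events: dict[tuple[str, str], list[GeneEvent]] | None = None,
    ):
        self.tree = tree
        self.transcripts = transcripts
        self.columns = columns
        self.costs = costs
        self.n_cols = len(columns)
        self.A = max((c.n_states for c in columns), default=0) + 1
        if events is None:
            events = gene_level_events(ancestral, tree)
        self.free = free_columns(events)
        self.events = events
        alpha = np.zeros((self.n_cols, self.A))
        for i, c in enumerate(columns):
            alpha[i, c.n_states + 1 :] = np.inf
        self.node_mask: dict[str, np.ndarray] = {}
        for node in tree.postorder():
            m = alpha.copy()
            for i, s in enumerate(ancestral[node]):
                if s is ExonState.ABSENT:
                    m[i, 1:] = np.inf
            self.node_mask[node] = m
        # per-leaf-gene observed profiles and relaxed ("any transcript") profile
        self.obs: dict[str, list[np.ndarray]] = {}
        self.relaxed: dict[str, np.ndarray] = {}
        for g in tree.leaves:
            ts = transcripts.get(g, [])
            profs = []
            rel = np.full((self.n_cols, self.A), np.inf)
            for t in ts:
                p = np.full((self.n_cols, self.A), np.inf)
                p[np.arange(self.n_cols), list(t.values)] = 0.0
                profs.append(p + self.node_mask[g])
                rel = np.minimum(rel, p)
            self.obs[g] = profs
            self.relaxed[g] = rel + self.node_mask[g] if ts else rel

    def free_idx(self, edge: tuple[str, str]) -> np.ndarray:
        return np.fromiter(sorted(self.free.get(edge, ())), dtype=int)

    def minterm(self, child_profile: np.ndarray, edge: tuple[str, str]) -> np.ndarray:
        """min_x { c(u, x) + profile[x] } per column, with free-column edges."""
        colmin = child_profile.min(axis=1)
        ce = self.costs.exon
        if math.isinf(ce):
            res = child_profile.copy()
        else:
            res = np.minimum(child_profile, colmin[:, None] + ce)
        fi = self.free_idx(edge)
        if fi.size:
            res[fi, :] = colmin[fi, None]
        return res


def exon_profile(
    ctx: ScoringContext,
    gene: str,
    left_profile: np.ndarray | None = None,
    right_profile: np.ndarray | None = None,
) -> np.ndarray:
    """Sankoff exon profile of a slot at ``gene`` from its children's profiles.

    Per column i and configuration u:
    ``t_iu = min_x{c(u,x)+r_ix} + min_y{c(u,y)+l_iy}`` with ``c(a,a)=0`` and
    ``c(a,b)=c_E`` otherwise, except that the change is free on an edge where
    the gene gained the exon as constitutive or lost it; all u>0 are infinite
    where the exon is absent from the gene.  A missing child contributes 0.
    """
    prof = ctx.node_mask[gene].copy()
    kids = ctx.tree.children(gene)
    for child_profile, side in ((left_profile, 0), (right_profile, 1)):
        if child_profile is not None:
            prof = prof + ctx.minterm(child_profile, (gene, kids[side]))
    return prof


def observed_profile(ctx: ScoringContext, gene: str, transcript_index: int) -> np.ndarray:
    return ctx.obs[gene][transcript_index]


def minMP(profile: np.ndarray) -> float:
    """Parsimony score of a slot: sum over columns of the best configuration."""
    return float(profile.min(axis=1).sum())


def tree_score(
    ctx: ScoringContext,
    shape: TreeShape,
    leaf_profiles: dict[str, np.ndarray],
    backtrack: bool = False,
) -> tuple[float, dict[str, tuple[int, ...]] | None]:
    """Exact Sankoff parsimony of one transcript tree given its leaf profiles.

    With ``backtrack`` the per-node configuration vectors are reconstructed
    (smallest configuration on ties, root downward).
    """
    tree = ctx.tree
    span = shape_span(tree, shape)
    prof: dict[str, np.ndarray] = {}
    order = [n for n in tree.postorder() if n in span]
    for n in order:
        if tree.is_leaf(n):
            prof[n] = leaf_profiles[n]
        else:
            p = ctx.node_mask[n].copy()
            for c in tree.children(n):
                if c in span:
                    p = p + ctx.minterm(prof[c], (n, c))
            prof[n] = p
    score = float(prof[shape.root].min(axis=1).sum())
    if not backtrack or math.isinf(score):
        return score, None
    vectors: dict[str, tuple[int, ...]] = {}
    choice: dict[str, np.ndarray] = {}
    choice[shape.root] = prof[shape.root].argmin(axis=1)
    for n in reversed(order):
        u = choice[n]
        vectors[n] = tuple(int(x) for x in u)
        if tree.is_leaf(n):
            continue
        for c in tree.children(n):
            if c not in span:
                continue
            ce = ctx.costs.exon
            P = prof[c]
            neq = np.arange(ctx.A)[None, :] != np.asarray(u)[:, None]
            if math.isinf(ce):
                cost = np.where(neq, np.inf, P)
            else:
                cost = P + ce * neq
            fi = ctx.free_idx((n, c))
            if fi.size:
                cost[fi] = P[fi]
            choice[c] = cost.argmin(axis=1)
    return score, vectors


def relaxed_tree_score(ctx: ScoringContext, shape: TreeShape) -> float:
    """Best parsimony of one tree as if all transcripts were available
    (each leaf slot may take any configuration some transcript of the gene
    shows) — a true lower bound on the tree's contribution to S_F."""
    score, _ = tree_score(
        ctx, shape, {g: ctx.relaxed[g] for g in shape.leaves}
    )
    return score


# ---------------------------------------------------------------------------
# the leaf-assignment dynamic program
# ---------------------------------------------------------------------------


@dataclass
class AssignedTree:
    """One transcript tree of a solution, with its leaf transcripts and
    reconstructed ancestral configuration vectors."""

    shape: TreeShape
    leaf_transcripts: dict[str, Transcript]
    vectors: dict[str, tuple[int, ...]] = field(default_factory=dict)

    def key(self):
        return (
            self.shape.root,
            tuple(sorted((g, t.id) for g, t in self.leaf_transcripts.items())),
        )


@dataclass
class ForestAssignment:
    trees: list[AssignedTree]
    s_f: float

    def key(self):
        return tuple(sorted(t.key() for t in self.trees))


@dataclass
class AssignmentResult:
    s_f: float
    assignments: list[ForestAssignment]
    dp_score: float


class _Entry:
    __slots__ = ("value", "profiles", "back", "committed")

    def __init__(self, value, profiles, back, committed):
        self.value = value
        self.profiles = profiles
        self.back = back
        self.committed = committed


def _scenarios(topo: Topology, gene: str) -> list[frozenset[int]]:
    """Possible root-slot sets at ``gene``: per shape class, choose which of
    the class's slot positions are the class's rooted trees."""
    positions = topo.slots(gene)
    by_class: dict[tuple, list[int]] = {}
    rooted: dict[tuple, int] = {}
    for pos, i in enumerate(positions):
        key = topo.box_key(i, gene)
        by_class.setdefault(key, []).append(pos)
        if topo.trees[i].root == gene:
            rooted[key] = rooted.get(key, 0) + 1
    per_class = []
    for key in sorted(by_class):
        r = rooted.get(key, 0)
        per_class.append(list(itertools.combinations(by_class[key], r)))
    return [
        frozenset(itertools.chain.from_iterable(combo))
        for combo in itertools.product(*per_class)
    ]


def assign_leaves(
    topo: Topology,
    tree: GeneTree,
    transcripts: dict[str, list[Transcript]],
    ancestral: ExonStateMatrix,
    costs: Costs,
    *,
    columns: list[ExonColumn] | None = None,
    ctx: ScoringContext | None = None,
    max_solutions: int = 10000,
) -> AssignmentResult:
    """Best leaf assignments of ``topo`` and the resulting S_F.

    Runs the postorder state dynamic program, backtracks every co-optimal
    pointer chain, assembles the forests, re-scores them exactly and returns
    all distinct assignments achieving the minimum.  Leaf states are kept at
    the identity ordering: the parent's pointer injections range over all
    matchings, so every leaf permutation is still explored.
    """
    if ctx is None:
        if columns is None:
            raise ValueError("need either columns or a ScoringContext")
        ctx = ScoringContext(tree, transcripts, columns, ancestral, costs)
    for g in tree.leaves:
        if len(topo.slots(g)) != len(transcripts.get(g, [])):
            raise ValueError(
                f"topology has {len(topo.slots(g))} slots at leaf {g!r} but "
                f"{len(transcripts.get(g, []))} transcripts are observed"
            )

    states: dict[str, list[State]] = {}
    tables: dict[str, dict[tuple[int, frozenset[int]], _Entry]] = {}
    side_info: dict[str, list[tuple]] = {}

    for g in tree.postorder():
        tables[g] = {}
        slots_g = topo.slots(g)
        if tree.is_leaf(g):
            states[g] = [State(g, order=tuple(range(len(slots_g))))]
            profiles = (
                np.stack([ctx.obs[g][i] for i in range(len(slots_g))])
                if slots_g
                else np.zeros((0, ctx.n_cols, ctx.A))
            )
            for U in _scenarios(topo, g):
                tables[g][(0, U)] = _Entry(0.0, profiles, [], None)
            continue

        cl, cr = tree.children(g)
        lefts = _injections(
            _slot_need_keys(topo, g, cl),
            [topo.box_key(j, cl) for j in topo.slots(cl)],
        )
        rights = _injections(
            _slot_need_keys(topo, g, cr),
            [topo.box_key(j, cr) for j in topo.slots(cr)],
        )
        states[g] = [State(g, left=l, right=r) for l in lefts for r in rights]
        side_info[g] = []
        mask = ctx.node_mask[g]
        n_slots = len(slots_g)
        scen = _scenarios(topo, g)
        root_candidates = sorted(set().union(*scen)) if scen else []
        # min-terms depend only on (child state, scenario, child slot): memoize
        memo: dict[tuple, dict[tuple, np.ndarray]] = {cl: {}, cr: {}}

        def side_terms(child, child_states, U_child, ptr):
            cache = memo[child]
            terms = []
            for si in child_states:
                t = np.zeros((n_slots, ctx.n_cols, ctx.A))
                for pos in range(n_slots):
                    p = ptr[pos]
                    if p is None:
                        continue
                    key = (si, U_child, p)
                    if key not in cache:
                        prof_c = tables[child][(si, U_child)].profiles
                        cache[key] = ctx.minterm(prof_c[p], (g, child))
                    t[pos] = cache[key]
                terms.append(t)
            return np.stack(terms) if terms else np.zeros(
                (0, n_slots, ctx.n_cols, ctx.A)
            )

        def side_info_for(child, ptr, cache):
            if ptr in cache:
                return cache[ptr]
            U = frozenset(
                set(range(len(topo.slots(child))))
                - {p for p in ptr if p is not None}
            )
            child_states = sorted({si for (si, u) in tables[child] if u == U})
            vals = np.array(
                [tables[child][(si, U)].value for si in child_states]
            )
            info = (U, child_states, vals, side_terms(child, child_states, U, ptr))
            cache[ptr] = info
            return info

        linfo_cache: dict = {}
        rinfo_cache: dict = {}
        for s_idx, st in enumerate(states[g]):
            U_L, l_states, valL, Lt = side_info_for(cl, st.left, linfo_cache)
            U_R, r_states, valR, Rt = side_info_for(cr, st.right, rinfo_cache)
            side_info[g].append((U_L, U_R))
            nL, nR = len(l_states), len(r_states)
            if nL == 0 or nR == 0:
                continue
            # pairwise minMP of every root-candidate slot
            M = {}
            for pos in root_candidates:
                pair = Lt[:, None, pos] + Rt[None, :, pos] + mask
                M[pos] = pair.min(axis=3).sum(axis=2)
            for U in scen:
                total = valL[:, None] + valR[None, :]
                for pos in U:
                    total = total + M[pos]
                best = float(total.min())
                if math.isinf(best):
                    continue
                ties = np.argwhere(total == best)
                back = [
                    (l_states[a], r_states[b]) for a, b in ties.tolist()
                ]
                a0, b0 = ties[0]
                profiles = Lt[a0] + Rt[b0] + mask
                tables[g][(s_idx, U)] = _Entry(
                    best, profiles, back, (l_states[a0], r_states[b0])
                )

    if logger.isEnabledFor(logging.DEBUG):
        for g in tree.postorder():
            logger.debug(
                "state table %s: %d states, %d entries",
                g,
                len(states[g]),
                len(tables[g]),
            )

    root = tree.root
    root_entries = [
        (key, e) for key, e in tables[root].items()
    ]
    if not root_entries:
        return AssignmentResult(math.inf, [], math.inf)
    dp_best = min(e.value for _, e in root_entries)
    if math.isinf(dp_best):
        return AssignmentResult(math.inf, [], math.inf)

    # -- backtracking: enumerate co-optimal pointer chains -----------------
    def chains(g: str, s_idx: int, U: frozenset[int]):
        if tree.is_leaf(g):
            yield {g: (s_idx, U)}
            return
        entry = tables[g][(s_idx, U)]
        cl, cr = tree.children(g)
        U_L, U_R = side_info[g][s_idx]
        for sl, sr in entry.back:
            for chL in chains(cl, sl, U_L):
                for chR in chains(cr, sr, U_R):
                    d = {g: (s_idx, U)}
                    d.update(chL)
                    d.update(chR)
                    yield d

    def all_chains():
        for (s_idx, U), e in sorted(root_entries, key=lambda kv: kv[0][0]):
            if e.value == dp_best:
                yield from chains(root, s_idx, U)

    candidates: dict[tuple, ForestAssignment] = {}
    for chain in itertools.islice(all_chains(), max_solutions):
        forest = _assemble(topo, tree, transcripts, states, chain)
        exact = 0.0
        for at in forest.trees:
            leaf_profs = {
                g: ctx.obs[g][transcripts[g].index(t)]
                for g, t in at.leaf_transcripts.items()
            }
            sc, vec = tree_score(ctx, at.shape, leaf_profs, backtrack=True)
            exact += sc
            at.vectors = vec or {}
        forest.s_f = exact
        candidates.setdefault(forest.key(), forest)

    if not candidates:
        return AssignmentResult(math.inf, [], dp_best)
    s_f = min(f.s_f for f in candidates.values())
    best = sorted(
        (f for f in candidates.values() if f.s_f == s_f), key=lambda f: f.key()
    )
    return AssignmentResult(s_f, best, dp_best)


def _assemble(
    topo: Topology,
    tree: GeneTree,
    transcripts: dict[str, list[Transcript]],
    states: dict[str, list[State]],
    chain: dict[str, tuple[int, frozenset[int]]],
) -> ForestAssignment:
    """Turn one pointer chain into an explicit forest of assigned trees."""
    trees_out: list[AssignedTree] = []
    for g in tree.postorder():
        s_idx, U = chain[g]
        for pos in sorted(U):
            leaf_map: dict[str, Transcript] = {}
            stack = [(g, pos)]
            while stack:
                node, p = stack.pop()
                st = states[node][chain[node][0]]
                if tree.is_leaf(node):
                    leaf_map[node] = transcripts[node][st.order[p]]
                    continue
                cl, cr = tree.children(node)
                if st.left[p] is not None:
                    stack.append((cl, st.left[p]))
                if st.right[p] is not None:
                    stack.append((cr, st.right[p]))
            trees_out.append(
                AssignedTree(TreeShape(g, tuple(leaf_map)), leaf_map)
            )
    return ForestAssignment(trees_out, math.inf)
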