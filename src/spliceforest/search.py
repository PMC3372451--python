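"""Search over transcript-forest topologies for all minimum-cost solutions.

The score of a solution is ``S = c_B*N_tree + c_D*N_death + S_F`` — the
structural part charges transcript births and deaths at constant cost, the
parsimony part S_F sums the maximum-parsimony score of each transcript tree.
Topologies are explored with increasing numbers of trees; each topology gets
a true lower bound (its structural cost plus each tree's best parsimony as if
all transcripts were available) and is discarded when the bound exceeds the
best score seen so far.  An initial incumbent comes from random sampling of
the search space so that pruning is effective from the start.  All solutions
of minimum cost are returned, ranked by total event count and then by the
mean leaf-similarity index of their trees.

The extended model replaces the constant birth cost of each tree by the
change distance of its root transcript to its closest ancestor transcript in
the solution; this removes the birth term from the lower bound, so the
extended search must visit every topology.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np

from .ancestral import (
    gene_level_events,
    leaf_exon_states,
    reconstruct_ancestral_exon_states,
)
from .assignment import (
    AssignmentResult,
    ForestAssignment,
    ScoringContext,
    assign_leaves,
    relaxed_tree_score,
    tree_score,
)
from .model import (
    Costs,
    ExonColumn,
    ExonStateMatrix,
    GeneTree,
    Transcript,
    ValidationError,
)
from .topology import Topology, TreeShape, is_valid

__all__ = [
    "Solution",
    "SearchOptions",
    "SearchResult",
    "score_solution",
    "topology_lower_bound",
    "sample_initial_upper_bound",
    "similarity_index",
    "infer_transcript_phylogenies",
    "extended_birth_cost",
]

logger = logging.getLogger("spliceforest")


@dataclass
class Solution:
    """One minimum-cost reconstruction: topology + assignment + scores."""

    topology: Topology
    assignment: ForestAssignment
    s_f: float
    n_tree: int
    n_death: int
    score: float
    similarity: list[float] = field(default_factory=list)
    n_events: int = 0
    birth_costs: list[float] | None = None  # extended model only

    @property
    def mean_similarity(self) -> float:
        return sum(self.similarity) / len(self.similarity) if self.similarity else 1.0

    def sort_key(self):
        return (
            self.n_events,
            -self.mean_similarity,
            self.topology.canonical_key,
            self.assignment.key(),
        )

    def tree_strings(self) -> list[str]:
        """Newick-like rendering of each transcript tree; a dagger marks a
        death on the corresponding gene edge."""
        out = []
        gt = self.topology.gene_tree
        for at in self.assignment.trees:
            span = {n for g in at.leaf_transcripts for n in gt.ancestors(g)}
            span = {
                n
                for n in span
                if at.shape.root in gt.ancestors(n)
            }

            def fmt(n: str) -> str:
                if gt.is_leaf(n):
                    return at.leaf_transcripts[n].id
                kids = [
                    fmt(c) if c in span else "†" for c in gt.children(n)
                ]
                return f"({','.join(kids)}){n}"

            out.append(fmt(at.shape.root))
        return out


def score_solution(
    n_tree: int, n_death: int, s_f: float, costs: Costs
) -> float:
    """Total score S = c_B*N_tree + c_D*N_death + S_F (infinities propagate)."""
    if math.isinf(s_f):
        return math.inf
    return costs.birth * n_tree + costs.death * n_death + s_f


def topology_lower_bound(
    topo: Topology,
    costs: Costs,
    ctx: ScoringContext,
    *,
    include_birth: bool = True,
) -> float:
    """True lower bound on the best solution using this topology.

    Structural part plus, per tree, the best relaxed parsimony computed as if
    all transcripts were available (trees do not compete for transcripts).
    """
    structural = costs.death * topo.n_death
    if include_birth:
        structural += costs.birth * topo.n_tree
    return structural + sum(relaxed_tree_score(ctx, s) for s in topo.trees)


def similarity_index(leaf_vectors: list[tuple[int, ...]]) -> float:
    """Leaf-sharing index of one tree, in [0, 1].

    Sums, over leaves, the exons of that leaf present in at least two leaves;
    divides by the number of exons present in at least one leaf times the
    number of leaves.  1 when all leaves share the same exons (or the tree has
    no included exon at all), 0 when every exon is private to its leaf.
    """
    if not leaf_vectors:
        raise ValueError("similarity index needs at least one leaf")
    included = [
        {i for i, v in enumerate(vec) if v >= 1} for vec in leaf_vectors
    ]
    counts: dict[int, int] = {}
    for s in included:
        for i in s:
            counts[i] = counts.get(i, 0) + 1
    denom = len(counts) * len(leaf_vectors)
    if denom == 0:
        return 1.0
    num = sum(1 for s in included for i in s if counts[i] >= 2)
    return num / denom


def _random_topology(
    gene_tree: GeneTree,
    leaf_counts: dict[str, int],
    t: int,
    rng: np.random.Generator,
) -> Topology | None:
    """One random valid t-tree topology, or None if the draw fails."""
    members: dict[int, set[str]] = {i: set() for i in range(t)}
    for g, k in leaf_counts.items():
        if k > t:
            return None
        for i in rng.choice(t, size=k, replace=False):
            members[int(i)].add(g)
    if any(not s for s in members.values()):
        return None
    shapes = []
    for s in members.values():
        anc = gene_tree.ancestors(gene_tree.lca(sorted(s)))
        root = anc[int(rng.integers(len(anc)))]
        shapes.append(TreeShape(root, tuple(s)))
    topo = Topology(gene_tree, shapes)
    return topo if is_valid(topo) else None


def sample_initial_upper_bound(
    gene_tree: GeneTree,
    transcripts: dict[str, list[Transcript]],
    costs: Costs,
    ctx: ScoringContext,
    samples_per_tree_count: int = 10,
    seed: int = 0,
    max_trees: int | None = None,
) -> float:
    """Minimum score among randomly drawn, randomly assigned configurations.

    Deterministic given the seed; every sampled configuration is a feasible
    solution, so the returned value is a true upper bound on the optimum.
    """
    if samples_per_tree_count < 1:
        raise ValueError("samples_per_tree_count must be >= 1")
    rng = np.random.default_rng(seed)
    leaf_counts = {g: len(transcripts.get(g, [])) for g in gene_tree.leaves}
    t_min = max(leaf_counts.values())
    t_max = sum(leaf_counts.values())
    if max_trees is not None:
        t_max = min(t_max, max_trees)
    best = math.inf
    for t in range(t_min, t_max + 1):
        drawn = 0
        for _ in range(samples_per_tree_count * 20):
            if drawn >= samples_per_tree_count:
                break
            topo = _random_topology(gene_tree, leaf_counts, t, rng)
            if topo is None:
                continue
            drawn += 1
            s_f = _random_assignment_score(topo, transcripts, ctx, rng)
            score = score_solution(topo.n_tree, topo.n_death, s_f, costs)
            best = min(best, score)
    return best


def _random_assignment_score(
    topo: Topology,
    transcripts: dict[str, list[Transcript]],
    ctx: ScoringContext,
    rng: np.random.Generator,
) -> float:
    perms = {
        g: list(rng.permutation(len(transcripts.get(g, []))))
        for g in topo.gene_tree.leaves
    }
    used = {g: 0 for g in perms}
    total = 0.0
    for shape in topo.trees:
        leaf_profs = {}
        for g in shape.leaves:
            idx = perms[g][used[g]]
            used[g] += 1
            leaf_profs[g] = ctx.obs[g][idx]
        sc, _ = tree_score(ctx, shape, leaf_profs)
        total += sc
    return total


@dataclass
class SearchOptions:
    extended: bool = False
    seed: int = 0
    samples_per_tree_count: int = 10
    max_trees: int | None = None
    prune: bool = True
    max_solutions: int = 10000
    extended_guard: int = 12


@dataclass
class SearchResult:
    solutions: list[Solution]
    score: float
    no_solution: bool
    stats: list[dict]
    ancestral: ExonStateMatrix | None = None

    @property
    def n_solutions(self) -> int:
        return len(self.solutions)

    def to_dict(self) -> dict:
        sols = []
        for s in self.solutions:
            sols.append(
                {
                    "score": s.score,
                    "s_f": s.s_f,
                    "n_tree": s.n_tree,
                    "n_death": s.n_death,
                    "n_events": s.n_events,
                    "similarity": s.similarity,
                    "mean_similarity": s.mean_similarity,
                    "trees": s.tree_strings(),
                    "birth_costs": s.birth_costs,
                    "ancestral_vectors": [
                        {node: list(vec) for node, vec in at.vectors.items()}
                        for at in s.assignment.trees
                    ],
                }
            )
        return {
            "no_solution": self.no_solution,
            "score": None if math.isinf(self.score) else self.score,
            "n_solutions": self.n_solutions,
            "solutions": sols,
            "search_stats": self.stats,
        }


def _count_events(sol_trees, topo: Topology, ctx: ScoringContext) -> int:
    """Secondary criterion: transcript-level column changes + births + deaths
    + gene-level events (zero-cost changes count as events too)."""
    changes = 0
    gt = ctx.tree
    for at in sol_trees:
        vec = at.vectors
        for p in vec:
            for c in gt.children(p):
                if c in vec:
                    changes += sum(
                        1 for a, b in zip(vec[p], vec[c]) if a != b
                    )
    gene_events = sum(len(v) for v in ctx.events.values())
    return changes + topo.n_tree + topo.n_death + gene_events


def extended_birth_cost(
    assignment: ForestAssignment,
    ctx: ScoringContext,
    fallback_birth: float,
) -> list[float]:
    """Dynamic birth costs: each tree's root transcript pays the change
    distance to its closest (least-cost) ancestor transcript among trees
    created earlier, at the same gene or above; the very first tree (no
    candidate ancestor) pays the constant cost."""
    gt = ctx.tree
    ce = ctx.costs.exon
    order = sorted(
        range(len(assignment.trees)),
        key=lambda i: (
            gt.depth(assignment.trees[i].shape.root),
            assignment.trees[i].key(),
        ),
    )
    costs_out = [0.0] * len(assignment.trees)
    placed: list[tuple[str, tuple[int, ...]]] = []  # (gene node, vector)
    for i in order:
        at = assignment.trees[i]
        root = at.shape.root
        root_vec = at.vectors.get(root)
        anc_genes = set(gt.ancestors(root))
        candidates = [
            vec for node, vec in placed if node in anc_genes
        ]
        if not candidates or root_vec is None:
            costs_out[i] = fallback_birth
        else:
            best = math.inf
            for vec in candidates:
                diff = sum(1 for a, b in zip(root_vec, vec) if a != b)
                best = min(best, 0.0 if diff == 0 else diff * ce)
            costs_out[i] = best
        placed.extend(at.vectors.items())
    return costs_out


def infer_transcript_phylogenies(
    gene_tree: GeneTree,
    transcripts: dict[str, list[Transcript]],
    columns: list[ExonColumn],
    costs: Costs,
    options: SearchOptions | None = None,
    *,
    ancestral: ExonStateMatrix | None = None,
) -> SearchResult:
    """Return every minimum-cost forest of transcript trees.

    Reconstructs ancestral exon states (first co-optimal Dollo labeling),
    samples an initial upper bound, then explores topologies breadth-first by
    tree count with lower-bound pruning.  Solutions are ranked by event count
    and mean similarity index; ties are deterministic.
    """
    options = options or SearchOptions()
    leaf_counts = {g: len(transcripts.get(g, [])) for g in gene_tree.leaves}
    if any(v < 1 for v in leaf_counts.values()):
        raise ValidationError("every leaf gene needs at least one transcript")
    if ancestral is None:
        rows = leaf_exon_states(
            {g: transcripts[g] for g in gene_tree.leaves}, len(columns)
        )
        ancestral = reconstruct_ancestral_exon_states(gene_tree, rows)
    events = gene_level_events(ancestral, gene_tree)
    ctx = ScoringContext(gene_tree, transcripts, columns, ancestral, costs, events)

    total = sum(leaf_counts.values())
    if options.extended and total > options.extended_guard:
        raise ValidationError(
            f"extended model guarded to <= {options.extended_guard} transcripts "
            f"(instance has {total}); raise SearchOptions.extended_guard to force"
        )
    t_max = total if options.max_trees is None else min(total, options.max_trees)

    incumbent = math.inf
    if options.samples_per_tree_count > 0:
        incumbent = sample_initial_upper_bound(
            gene_tree,
            transcripts,
            costs,
            ctx,
            options.samples_per_tree_count,
            options.seed,
            options.max_trees,
        )
        logger.info("sampling upper bound: %s", incumbent)

    best_score = math.inf
    best: dict[tuple, tuple[Topology, ForestAssignment, float, list[float] | None]] = {}
    stats: list[dict] = []
    t_min = max(leaf_counts.values())

    # per-shape lower bound on its contribution to any solution score:
    # birth (basic model) + deaths + relaxed parsimony of the tree alone
    from .topology import all_tree_shapes, shape_deaths

    shape_costs: dict = {}
    for shape in all_tree_shapes(gene_tree):
        shape_costs[shape] = (
            (0.0 if options.extended else costs.birth)
            + costs.death * shape_deaths(gene_tree, shape)
            + relaxed_tree_score(ctx, shape)
        )

    # the extended model has no useful birth-cost bound: full enumeration
    pruning = options.prune and not options.extended
    for t in range(t_min, t_max + 1):
        bound_now = min(incumbent, best_score)
        if pruning and costs.birth > 0 and costs.birth * t > bound_now:
            break
        death_budget = None
        if pruning and costs.death > 0 and not math.isinf(bound_now):
            death_budget = (bound_now - costs.birth * t) / costs.death
            if death_budget < 0:
                continue
        generated = pruned = refined = 0
        cost_budget = min(incumbent, best_score) if pruning else None
        for topo in _level(
            gene_tree, leaf_counts, t, death_budget,
            shape_costs if pruning else None, cost_budget,
        ):
            generated += 1
            lb = sum(shape_costs[s] for s in topo.trees)
            if pruning and lb > min(incumbent, best_score):
                pruned += 1
                continue
            refined += 1
            res = assign_leaves(
                topo,
                gene_tree,
                transcripts,
                ancestral,
                costs,
                ctx=ctx,
                max_solutions=options.max_solutions,
            )
            if math.isinf(res.s_f):
                continue
            for fa in res.assignments:
                if options.extended:
                    bc = extended_birth_cost(fa, ctx, costs.birth)
                    score = sum(bc) + costs.death * topo.n_death + fa.s_f
                else:
                    bc = None
                    score = score_solution(
                        topo.n_tree, topo.n_death, fa.s_f, costs
                    )
                if score < best_score:
                    best_score = score
                    best = {}
                if score == best_score:
                    best.setdefault(
                        (topo.canonical_key, fa.key()), (topo, fa, fa.s_f, bc)
                    )
            incumbent = min(incumbent, best_score)
        stats.append(
            {"t": t, "generated": generated, "pruned": pruned, "refined": refined}
        )
        logger.info(
            "tree count %d: %d topologies, %d pruned, %d refined",
            t,
            generated,
            pruned,
            refined,
        )

    if not best:
        return SearchResult([], math.inf, True, stats, ancestral)

    solutions = []
    for topo, fa, s_f, bc in best.values():
        sims = [
            similarity_index([t.values for t in at.leaf_transcripts.values()])
            for at in fa.trees
        ]
        sol = Solution(
            topology=topo,
            assignment=fa,
            s_f=s_f,
            n_tree=topo.n_tree,
            n_death=topo.n_death,
            score=best_score,
            similarity=sims,
            birth_costs=bc,
        )
        sol.n_events = _count_events(fa.trees, topo, ctx)
        solutions.append(sol)
    if options.extended:
        # keep only assignments of minimum total birth cost
        min_birth = min(sum(s.birth_costs) for s in solutions)
        solutions = [s for s in solutions if sum(s.birth_costs) == min_birth]
    solutions.sort(key=Solution.sort_key)
    return SearchResult(solutions, best_score, False, stats, ancestral)


def _level(gene_tree, leaf_counts, t, death_budget, shape_costs, cost_budget):
    """Valid t-tree topologies in canonical order."""
    from .topology import _level_topologies

    level = _level_topologies(
        gene_tree, leaf_counts, t, death_budget, shape_costs, cost_budget
    )
    level.sort(key=lambda tp: tp.canonical_key)
    for tp in level:
        if is_valid(tp):
            yield tp
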