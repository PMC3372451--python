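"""Synthetic instance generation and brute-force validation.

The generator mirrors the two-level model: starting from ``n_T`` ancestral
transcripts and ``n_E`` exons at the root, each gene exon is born or dies
independently along every gene-tree edge, and transcripts gain or lose exons
depending on the current gene structure; transcripts may die or be duplicated
(a copy plus one random flip) at any edge.  Caterpillar gene trees — one leaf
child at every internal node — are the hardest shape for a given leaf count
and are the benchmark substrate.

The brute-force oracle enumerates every transcript assignment of a topology
(and, over all topologies, uses a forest constructor independent of the main
enumerator: restricted-growth partitions of the leaf slots plus explicit root
placement) and returns the exact optimum, against which the heuristic leaf
assignment is measured.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .ancestral import leaf_exon_states, reconstruct_ancestral_exon_states
from .assignment import ScoringContext, assign_leaves, tree_score
from .model import (
    Costs,
    ExonColumn,
    ExonState,
    ExonStateMatrix,
    GeneTree,
    Instance,
    Transcript,
    ValidationError,
)
from .search import SearchOptions, infer_transcript_phylogenies, score_solution
from .topology import Topology, TreeShape, is_valid, shape_deaths

__all__ = [
    "SimulationConfig",
    "SimulatedInstance",
    "make_caterpillar",
    "simulate",
    "enumerate_all_topologies",
    "brute_force_optimal",
    "BruteForceResult",
    "benchmark_optimality",
]

logger = logging.getLogger("spliceforest")


def make_caterpillar(n_leaves: int) -> GeneTree:
    """Caterpillar gene tree: every internal node has a leaf child; depth
    equals ``n_leaves - 1``."""
    if n_leaves < 2:
        raise ValueError("a caterpillar needs at least two leaves")
    children: dict[str, tuple[str, str]] = {}
    node = "g1"
    for i in range(2, n_leaves + 1):
        inner = f"a{i - 1}"
        children[inner] = (node, f"g{i}")
        node = inner
    return GeneTree(node, children)


@dataclass
class SimulationConfig:
    """Event rates of the generator (per edge, per exon or transcript)."""

    n_exons: int = 100
    n_transcripts: int | None = None  # None: drawn uniformly from {1,...,4}
    p_exon_birth: float = 0.05
    p_exon_death: float = 0.05
    p_gain: float = 0.05
    p_loss: float = 0.05
    p_transcript_death: float = 0.05
    p_transcript_birth: float = 0.05
    seed: int = 0

    def __post_init__(self):
        for name in (
            "p_exon_birth",
            "p_exon_death",
            "p_gain",
            "p_loss",
            "p_transcript_death",
            "p_transcript_birth",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValidationError(f"{name}={v} outside [0, 1]")
        if self.n_exons < 1:
            raise ValidationError("n_exons must be >= 1")
        if self.n_transcripts is not None and self.n_transcripts < 1:
            raise ValidationError("n_transcripts must be >= 1")


@dataclass
class SimulatedInstance:
    instance: Instance
    true_matrix: ExonStateMatrix
    lineages: dict[str, list[int]]  # transcript lineage ids per gene node
    lineage_parent: dict[int, int | None]
    n_births: int  # tree roots in the true history (incl. the ancestral ones)
    n_deaths: int
    n_changes: int  # transcript-level exon flips not forced by gene events
    dollo_violated: bool
    resampled_nodes: list[str] = field(default_factory=list)

    def true_score(self, costs: Costs) -> float:
        """Parsimony cost of the generating history itself."""
        return (
            costs.birth * self.n_births
            + costs.death * self.n_deaths
            + costs.exon * self.n_changes
        )


def simulate(tree: GeneTree, config: SimulationConfig) -> SimulatedInstance:
    """Evolve gene structure and transcripts along the tree (seeded)."""
    rng = np.random.default_rng(config.seed)
    ncol = config.n_exons
    n_t = config.n_transcripts or int(rng.integers(1, 5))

    root_states = [
        ExonState.CONSTITUTIVE if rng.random() < 0.5 else ExonState.ALTERNATIVE
        for _ in range(ncol)
    ]
    next_lineage = itertools.count()
    lineage_parent: dict[int, int | None] = {}

    def new_root_transcript() -> tuple[int, list[int]]:
        vec = [
            1
            if s is ExonState.CONSTITUTIVE or rng.random() < 0.5
            else 0
            for s in root_states
        ]
        if not any(vec):
            vec[int(rng.integers(ncol))] = 1
        lid = next(next_lineage)
        lineage_parent[lid] = None
        return lid, vec

    counters = {"births": 0, "deaths": 0, "changes": 0}
    origins = [1] * ncol  # root presence is the first origin of every column
    states: dict[str, list[ExonState]] = {tree.root: root_states}
    pool: dict[str, list[tuple[int, list[int]]]] = {
        tree.root: [new_root_transcript() for _ in range(n_t)]
    }
    counters["births"] += n_t
    lineages: dict[str, list[int]] = {}
    resampled: list[str] = []

    order = [n for n in reversed(tree.postorder())]  # preorder
    for node in order:
        lineages[node] = [lid for lid, _ in pool[node]]
        for child in tree.children(node):
            pstates = states[node]
            cstates = list(pstates)
            forced_one: set[int] = set()
            forced_zero: set[int] = set()
            for i in range(ncol):
                if pstates[i] is ExonState.ABSENT:
                    if rng.random() < config.p_exon_birth:
                        cstates[i] = (
                            ExonState.CONSTITUTIVE
                            if rng.random() < 0.5
                            else ExonState.ALTERNATIVE
                        )
                        origins[i] += 1
                        if cstates[i] is ExonState.CONSTITUTIVE:
                            forced_one.add(i)
                elif rng.random() < config.p_exon_death:
                    cstates[i] = ExonState.ABSENT
                    forced_zero.add(i)
            kids: list[tuple[int, list[int]]] = []
            for lid, vec in pool[node]:
                if rng.random() < config.p_transcript_death:
                    counters["deaths"] += 1
                    continue
                new = list(vec)
                for i in range(ncol):
                    if cstates[i] is ExonState.ABSENT:
                        new[i] = 0
                    elif i in forced_one:
                        new[i] = 1  # constitutive gain at the gene level: free
                    elif cstates[i] is ExonState.CONSTITUTIVE:
                        new[i] = max(new[i], 1)
                    else:  # alternative in the child gene
                        if new[i] and rng.random() < config.p_loss:
                            new[i] = 0
                            counters["changes"] += 1
                        elif not new[i] and rng.random() < config.p_gain:
                            new[i] = 1
                            counters["changes"] += 1
                clid = next(next_lineage)
                lineage_parent[clid] = lid
                kids.append((clid, new))
            if not kids:
                lid, vec = pool[node][int(rng.integers(len(pool[node])))]
                new = list(vec)
                for i in range(ncol):
                    if cstates[i] is ExonState.ABSENT:
                        new[i] = 0
                    elif i in forced_one or cstates[i] is ExonState.CONSTITUTIVE:
                        new[i] = max(new[i], 1)
                clid = next(next_lineage)
                lineage_parent[clid] = lid
                kids.append((clid, new))
                resampled.append(child)
                logger.info("revived an extinct transcript lineage at %s", child)
            for lid, vec in list(kids):
                if rng.random() < config.p_transcript_birth:
                    copy = list(vec)
                    alt_cols = [
                        i
                        for i in range(ncol)
                        if cstates[i] is ExonState.ALTERNATIVE
                    ]
                    if alt_cols:
                        j = alt_cols[int(rng.integers(len(alt_cols)))]
                        copy[j] = 0 if copy[j] else 1
                    blid = next(next_lineage)
                    lineage_parent[blid] = lid
                    kids.append((blid, copy))
                    counters["births"] += 1
            states[child] = cstates
            pool[child] = kids

    columns = [ExonColumn(f"e{i + 1}") for i in range(ncol)]
    transcripts: dict[str, list[Transcript]] = {}
    for g in tree.leaves:
        transcripts[g] = [
            Transcript(f"{g}.t{j + 1}", g, tuple(vec))
            for j, (_, vec) in enumerate(pool[g])
        ]
    instance = Instance(tree, transcripts, columns)
    matrix = ExonStateMatrix({n: tuple(states[n]) for n in tree.postorder()})
    return SimulatedInstance(
        instance=instance,
        true_matrix=matrix,
        lineages=lineages,
        lineage_parent=lineage_parent,
        n_births=counters["births"],
        n_deaths=counters["deaths"],
        n_changes=counters["changes"],
        dollo_violated=any(o > 1 for o in origins),
        resampled_nodes=resampled,
    )


# ---------------------------------------------------------------------------
# independent topology enumeration (restricted-growth partitions)
# ---------------------------------------------------------------------------


_PARTITION_CACHE: dict = {}


def _slot_partitions(tree: GeneTree, leaf_counts: dict[str, int], max_blocks: int):
    """All partitions of the leaf slots into blocks with per-gene-distinct
    membership, as sorted tuples of gene tuples (each partition once)."""
    cache_key = (
        tuple(tree.edges()),
        tuple(sorted(leaf_counts.items())),
        max_blocks,
    )
    if cache_key in _PARTITION_CACHE:
        return _PARTITION_CACHE[cache_key]
    slots = [g for g in tree.leaves for _ in range(leaf_counts[g])]
    seen = set()
    out = []

    def rec(i: int, blocks: list[set[str]]):
        if i == len(slots):
            key = tuple(sorted(tuple(sorted(b)) for b in blocks))
            if key not in seen:
                seen.add(key)
                out.append(key)
            return
        g = slots[i]
        for b in blocks:
            if g not in b:
                b.add(g)
                rec(i + 1, blocks)
                b.remove(g)
        if len(blocks) < max_blocks:
            blocks.append({g})
            rec(i + 1, blocks)
            blocks.pop()

    rec(0, [])
    if len(_PARTITION_CACHE) > 64:
        _PARTITION_CACHE.clear()
    _PARTITION_CACHE[cache_key] = out
    return out


def enumerate_all_topologies(
    tree: GeneTree,
    leaf_counts: dict[str, int],
    max_trees: int | None = None,
    *,
    death_budget: float | None = None,
    valid_only: bool = True,
    limit: int | None = None,
) -> list[Topology]:
    """Every topology, built directly: partition the leaf slots into trees,
    then place each tree root at any ancestor of its leaf set's LCA.

    This construction is independent of :func:`~spliceforest.topology.
    enumerate_topologies` and serves as its oracle in tests and as the
    exhaustive space of the brute-force benchmark.
    """
    total = sum(leaf_counts.values())
    cap = total if max_trees is None else min(total, max_trees)
    budget = math.inf if death_budget is None else death_budget
    out: list[Topology] = []
    seen = set()
    for part in _slot_partitions(tree, leaf_counts, cap):
        blocks = [list(b) for b in part]
        anc_opts = []
        for b in blocks:
            anc_opts.append(tree.ancestors(tree.lca(b)))
        for roots in itertools.product(*anc_opts):
            shapes = [TreeShape(r, tuple(b)) for r, b in zip(roots, blocks)]
            topo = Topology(tree, shapes)
            if topo.n_death > budget:
                continue
            if topo.canonical_key in seen:
                continue
            seen.add(topo.canonical_key)
            if not valid_only or is_valid(topo):
                out.append(topo)
                if limit is not None and len(out) > limit:
                    return out
    out.sort(key=lambda tp: (tp.n_tree, tp.canonical_key))
    return out


# ---------------------------------------------------------------------------
# brute-force oracle
# ---------------------------------------------------------------------------


def _oracle_topology_sf(
    topo: Topology,
    ctx: ScoringContext,
    transcripts: dict[str, list[Transcript]],
    guard: int = 10**6,
) -> float:
    """Exact minimum S_F of one topology by exhausting every assignment."""
    tree = ctx.tree
    space = 1
    for g in tree.leaves:
        space *= math.factorial(len(transcripts.get(g, [])))
    if space > guard:
        raise ValidationError(
            f"assignment space {space} exceeds the oracle guard {guard}"
        )
    slot_pos = {
        g: {ti: p for p, ti in enumerate(topo.slots(g))} for g in tree.leaves
    }
    tables = []
    for ti, shape in enumerate(topo.trees):
        gs = sorted(shape.leaves)
        table: dict[tuple[int, ...], float] = {}
        for choice in itertools.product(
            *[range(len(transcripts[g])) for g in gs]
        ):
            leaf_profs = {g: ctx.obs[g][c] for g, c in zip(gs, choice)}
            table[choice] = tree_score(ctx, shape, leaf_profs)[0]
        tables.append((gs, table))
    best = math.inf
    genes = list(tree.leaves)
    for perms in itertools.product(
        *[itertools.permutations(range(len(transcripts[g]))) for g in genes]
    ):
        pm = dict(zip(genes, perms))
        total = 0.0
        for ti, (gs, table) in enumerate(tables):
            choice = tuple(pm[g][slot_pos[g][ti]] for g in gs)
            total += table[choice]
        best = min(best, total)
    return best


@dataclass
class BruteForceResult:
    score: float
    topologies: list[tuple[Topology, float]]  # minimum-score topologies + S_F


def brute_force_optimal(
    instance: Instance,
    costs: Costs,
    topology: Topology | str = "all",
    *,
    ancestral: ExonStateMatrix | None = None,
    guard: int = 10**6,
    max_trees: int | None = None,
) -> BruteForceResult:
    """Exact optimum by exhaustive enumeration (guarded).

    With a single topology, every transcript assignment is scored; with
    ``"all"``, topologies come from the independent forest constructor and
    structurally hopeless ones are skipped once a better score is known
    (sound: the structural part alone is a lower bound).
    """
    tree = instance.tree
    transcripts = instance.transcripts
    if ancestral is None:
        rows = leaf_exon_states(transcripts, len(instance.columns))
        ancestral = reconstruct_ancestral_exon_states(tree, rows)
    ctx = ScoringContext(tree, transcripts, instance.columns, ancestral, costs)

    if isinstance(topology, Topology):
        sf = _oracle_topology_sf(topology, ctx, transcripts, guard)
        sc = score_solution(topology.n_tree, topology.n_death, sf, costs)
        return BruteForceResult(sc, [(topology, sf)])

    leaf_counts = instance.leaf_counts()
    total = sum(leaf_counts.values())
    cap = total if max_trees is None else min(total, max_trees)
    parts = sorted(_slot_partitions(tree, leaf_counts, cap), key=len)
    best = math.inf
    keep: list[tuple[Topology, float]] = []
    seen: set = set()

    # per-shape contribution floor: birth + deaths + relaxed parsimony.
    # Elevating a tree root only adds edges, so the LCA-rooted floor of a
    # block is a true lower bound for any root placement of that block.
    from .assignment import relaxed_tree_score

    weight_cache: dict[TreeShape, float] = {}

    def weight(shape: TreeShape) -> float:
        if shape not in weight_cache:
            weight_cache[shape] = (
                costs.birth
                + costs.death * shape_deaths(tree, shape)
                + relaxed_tree_score(ctx, shape)
            )
        return weight_cache[shape]

    for part in parts:
        t = len(part)
        if costs.birth * t > best:
            continue
        blocks = [list(b) for b in part]
        base_shapes = [TreeShape(tree.lca(b), tuple(b)) for b in blocks]
        base_w = [weight(s) for s in base_shapes]
        if sum(base_w) > best:
            continue
        anc_opts = [tree.ancestors(s.root) for s in base_shapes]

        def place(i: int, shapes: list[TreeShape], w_used: float):
            nonlocal best, keep
            if w_used + sum(base_w[i:]) > best:
                return
            if i == len(blocks):
                topo = Topology(tree, shapes)
                if topo.canonical_key in seen or not is_valid(topo):
                    seen.add(topo.canonical_key)
                    return
                seen.add(topo.canonical_key)
                sf = _oracle_topology_sf(topo, ctx, transcripts, guard)
                sc = score_solution(topo.n_tree, topo.n_death, sf, costs)
                if sc < best:
                    best = sc
                    keep = [(topo, sf)]
                elif sc == best and not math.isinf(sc):
                    keep.append((topo, sf))
                return
            for root in anc_opts[i]:
                shape = TreeShape(root, base_shapes[i].leaves)
                place(i + 1, shapes + [shape], w_used + weight(shape))
            return

        place(0, [], 0.0)
    return BruteForceResult(best, keep)


# ---------------------------------------------------------------------------
# benchmark
# ---------------------------------------------------------------------------


def _structural_space_size(
    tree: GeneTree, leaf_counts: dict[str, int], parts=None
) -> int:
    """Number of structurally distinct forests (before the connectivity
    filter): per slot partition, each block's root ranges over the ancestors
    of its LCA; identical blocks pick roots as an unordered multiset."""
    if parts is None:
        parts = _slot_partitions(tree, leaf_counts, sum(leaf_counts.values()))
    total = 0
    for part in parts:
        prod = 1
        for block, mult in ((b, part.count(b)) for b in set(part)):
            n_anc = len(tree.ancestors(tree.lca(block)))
            prod *= math.comb(n_anc + mult - 1, mult)
        total += prod
    return total


def _sampled_topologies(
    tree: GeneTree,
    leaf_counts: dict[str, int],
    cap: int,
    rng: np.random.Generator,
):
    """Valid topologies for the optimality comparison: the full space when it
    fits ``cap``, otherwise a cluster sample (random partitions, all their
    root placements) of about ``cap`` topologies."""
    parts = list(
        _slot_partitions(tree, leaf_counts, sum(leaf_counts.values()))
    )
    order = rng.permutation(len(parts))
    out: list[Topology] = []
    seen: set = set()
    exhausted = True
    for idx in order:
        if len(out) >= cap:
            exhausted = False
            break
        blocks = [list(b) for b in parts[idx]]
        anc_opts = [tree.ancestors(tree.lca(b)) for b in blocks]
        for roots in itertools.product(*anc_opts):
            if len(out) >= cap:
                exhausted = False
                break
            topo = Topology(
                tree, [TreeShape(r, tuple(b)) for r, b in zip(roots, blocks)]
            )
            if topo.canonical_key in seen:
                continue
            seen.add(topo.canonical_key)
            if is_valid(topo):
                out.append(topo)
    return out, exhausted, parts


def benchmark_optimality(
    n_runs: int,
    leaf_sizes: list[int],
    transcripts_per_gene: list[int],
    costs: Costs,
    seed: int = 0,
    *,
    n_exons: int = 20,
    config: SimulationConfig | None = None,
    sample_topologies: int = 400,
    oracle_guard: int = 10**6,
) -> pd.DataFrame:
    """Leaf-assignment optimality and pruning statistics on caterpillar trees.

    Per topology of every simulated run, the heuristic leaf-assignment score
    is compared with the exhaustive assignment optimum: ``optimality_pct`` is
    the percentage of topologies where the two agree and ``mean_diff`` /
    ``sd_diff`` summarize the per-topology gap.  When a run's topology space
    exceeds ``sample_topologies`` the comparison uses a seeded cluster sample
    of that size (whole partitions at a time) — the exhaustive oracle bounds
    the sizes that can be swept in full.  ``topologies_total`` is the exact
    structural space size and ``topologies_refined_pct`` the share of it that
    the pruned search passed to the leaf assignment.
    """
    rows = []
    rng = np.random.default_rng(seed)
    for n_leaves in leaf_sizes:
        for n_t in transcripts_per_gene:
            diffs: list[float] = []
            matches = 0
            compared = 0
            space_sizes = []
            refined_pcts = []
            effective = 0
            for _ in range(n_runs):
                run_seed = int(rng.integers(2**31))
                base = config or SimulationConfig(n_exons=n_exons)
                cfg = SimulationConfig(
                    n_exons=base.n_exons,
                    n_transcripts=n_t,
                    p_exon_birth=base.p_exon_birth,
                    p_exon_death=base.p_exon_death,
                    p_gain=base.p_gain,
                    p_loss=base.p_loss,
                    p_transcript_death=base.p_transcript_death,
                    p_transcript_birth=base.p_transcript_birth,
                    seed=run_seed,
                )
                tree = make_caterpillar(n_leaves)
                sim = simulate(tree, cfg)
                inst = sim.instance
                space = 1
                for g in tree.leaves:
                    space *= math.factorial(len(inst.transcripts[g]))
                if space > oracle_guard:
                    logger.info("run skipped: assignment space %d", space)
                    continue
                effective += 1
                rows_ls = leaf_exon_states(inst.transcripts, len(inst.columns))
                ancestral = reconstruct_ancestral_exon_states(tree, rows_ls)
                ctx = ScoringContext(
                    tree, inst.transcripts, inst.columns, ancestral, costs
                )
                topos, _, parts = _sampled_topologies(
                    tree, inst.leaf_counts(), sample_topologies, rng
                )
                total_structural = _structural_space_size(
                    tree, inst.leaf_counts(), parts
                )
                for topo in topos:
                    oracle = _oracle_topology_sf(
                        topo, ctx, inst.transcripts, oracle_guard
                    )
                    res = assign_leaves(
                        topo,
                        tree,
                        inst.transcripts,
                        ancestral,
                        costs,
                        ctx=ctx,
                        max_solutions=1,
                    )
                    compared += 1
                    diffs.append(res.s_f - oracle)
                    if res.s_f == oracle:
                        matches += 1
                space_sizes.append(total_structural)
                # pruning statistics only: solution enumeration capped
                search = infer_transcript_phylogenies(
                    tree,
                    inst.transcripts,
                    inst.columns,
                    costs,
                    SearchOptions(seed=run_seed, max_solutions=4),
                    ancestral=ancestral,
                )
                refined = sum(s["refined"] for s in search.stats)
                refined_pcts.append(100.0 * refined / total_structural)
            rows.append(
                {
                    "leaves": n_leaves,
                    "transcripts": n_t,
                    "runs": effective,
                    "optimality_pct": 100.0 * matches / compared if compared else float("nan"),
                    "mean_diff": float(np.mean(diffs)) if diffs else float("nan"),
                    "sd_diff": float(np.std(diffs)) if diffs else float("nan"),
                    "topologies_total": float(np.mean(space_sizes))
                    if space_sizes
                    else float("nan"),
                    "topologies_refined_pct": float(np.mean(refined_pcts))
                    if refined_pcts
                    else float("nan"),
                }
            )
    return pd.DataFrame(rows)
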