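"""Ancestral gene exon states: small parsimony under a Dollo constraint.

Each exon column evolves independently on the gene tree over the three states
absent / alternative / constitutive, every transition costing one unit.  The
Dollo constraint forbids an exon from being created twice: over the whole tree
a column may have at most one ABSENT→present origin (a present root counts as
the origin).

The reconstruction runs one dynamic program per column over the possible
origin nodes.  Below the origin the exon may be lost but never regained; above
and outside it every gene is ABSENT.  This is exactly the minimum-transition
labeling among all Dollo-consistent labelings, so it coincides with plain
Sankoff small parsimony whenever some Sankoff optimum happens to respect
Dollo, and otherwise yields the best single-origin relabeling.
"""

from __future__ import annotations

import enum
import itertools
import math
from dataclasses import dataclass

from .model import ExonState, ExonStateMatrix, GeneTree, Transcript, ValidationError

__all__ = [
    "leaf_exon_states",
    "reconstruct_ancestral_exon_states",
    "all_ancestral_labelings",
    "GeneEventKind",
    "GeneEvent",
    "gene_level_events",
]

_PRESENT = (ExonState.ALTERNATIVE, ExonState.CONSTITUTIVE)


def leaf_exon_states(
    transcripts: dict[str, list[Transcript]], n_columns: int
) -> dict[str, tuple[ExonState, ...]]:
    """Derive per-leaf exon states from the observed transcripts.

    A column is CONSTITUTIVE in a leaf gene iff every transcript includes it
    (value >= 1), ALTERNATIVE iff some but not all do, ABSENT iff none does.
    Leaf states are inferred purely from transcripts: a present-but-never-
    spliced-in exon is indistinguishable from an absent one.
    """
    rows: dict[str, tuple[ExonState, ...]] = {}
    for gene, ts in transcripts.items():
        if not ts:
            raise ValidationError(f"leaf gene {gene!r} has no transcripts")
        states = []
        for i in range(n_columns):
            included = sum(1 for t in ts if t.values[i] >= 1)
            if included == 0:
                states.append(ExonState.ABSENT)
            elif included == len(ts):
                states.append(ExonState.CONSTITUTIVE)
            else:
                states.append(ExonState.ALTERNATIVE)
        rows[gene] = tuple(states)
    return rows


def _column_labelings(
    tree: GeneTree, leaf_state: dict[str, ExonState]
) -> tuple[int, list[dict[str, ExonState]]]:
    """All minimum-transition Dollo-consistent labelings of one column."""
    present_leaves = [g for g in tree.leaves if leaf_state[g].present]
    if not present_leaves:
        lab = {n: ExonState.ABSENT for n in tree.postorder()}
        for g in tree.leaves:
            lab[g] = leaf_state[g]
        return 0, [lab]

    # down(v, s): min transitions in subtree(v) with state(v)=s and no regain.
    down: dict[tuple[str, ExonState], float] = {}
    has_present: dict[str, bool] = {}
    for v in tree.postorder():
        if tree.is_leaf(v):
            has_present[v] = leaf_state[v].present
            for s in ExonState:
                down[(v, s)] = 0.0 if s is leaf_state[v] else math.inf
        else:
            l, r = tree.children(v)
            has_present[v] = has_present[l] or has_present[r]
            for s in ExonState:
                if s is ExonState.ABSENT:
                    down[(v, s)] = 0.0 if not has_present[v] else math.inf
                    continue
                total = 0.0
                for c in (l, r):
                    total += min(
                        (1.0 if sc is not s else 0.0) + down[(c, sc)]
                        for sc in ExonState
                    )
                down[(v, s)] = total

    lca = tree.lca(present_leaves)
    best = math.inf
    origins: list[tuple[str, ExonState, float]] = []
    for origin in tree.ancestors(lca):  # lca, parent(lca), ..., root
        gain = 0.0 if origin == tree.root else 1.0
        for s in _PRESENT:
            cost = gain + down[(origin, s)]
            origins.append((origin, s, cost))
            best = min(best, cost)

    labelings: list[dict[str, ExonState]] = []
    node_order = sorted(tree.postorder())
    state_key = {s: s.order for s in ExonState}

    def expansions(v: str, s: ExonState) -> list[dict[str, ExonState]]:
        """All labelings of subtree(v) with state(v)=s at cost down[(v, s)]."""
        if tree.is_leaf(v):
            return [{v: s}]
        out: list[dict[str, ExonState]] = []
        per_child: list[list[dict[str, ExonState]]] = []
        for c in tree.children(v):
            allowed = (ExonState.ABSENT,) if s is ExonState.ABSENT else ExonState
            costs = {
                sc: (1.0 if sc is not s else 0.0) + down[(c, sc)]
                for sc in allowed
            }
            mc = min(costs.values())
            subs: list[dict[str, ExonState]] = []
            for sc, cost in costs.items():
                if cost == mc:
                    subs.extend(expansions(c, sc))
            per_child.append(subs)
        for sub_l, sub_r in itertools.product(*per_child):
            lab = {v: s}
            lab.update(sub_l)
            lab.update(sub_r)
            out.append(lab)
        return out

    for origin, s, cost in origins:
        if cost != best:
            continue
        base = {n: ExonState.ABSENT for n in tree.postorder()}
        for sub in expansions(origin, s):
            lab = dict(base)
            lab.update(sub)
            labelings.append(lab)

    # deterministic order: lexicographic over sorted node ids, ABSENT<ALT<CONST
    labelings.sort(key=lambda lab: tuple(state_key[lab[n]] for n in node_order))
    # distinct origins can coincide only if identical dicts slipped in; dedupe
    unique = []
    seen = set()
    for lab in labelings:
        key = tuple(lab[n].value for n in node_order)
        if key not in seen:
            seen.add(key)
            unique.append(lab)
    return int(best), unique


def reconstruct_ancestral_exon_states(
    tree: GeneTree, leaf_states: dict[str, tuple[ExonState, ...]]
) -> ExonStateMatrix:
    """Minimum-transition Dollo-consistent ancestral matrix (first co-optimum).

    Ties are broken deterministically: per column, the labeling that is
    lexicographically smallest over node ids sorted alphabetically with state
    order ABSENT < ALTERNATIVE < CONSTITUTIVE.
    """
    ncol = len(next(iter(leaf_states.values())))
    per_node: dict[str, list[ExonState]] = {n: [] for n in tree.postorder()}
    for i in range(ncol):
        col = {g: leaf_states[g][i] for g in tree.leaves}
        _, labs = _column_labelings(tree, col)
        first = labs[0]
        for n in tree.postorder():
            per_node[n].append(first[n])
    return ExonStateMatrix({n: tuple(v) for n, v in per_node.items()})


def all_ancestral_labelings(
    tree: GeneTree, leaf_states: dict[str, tuple[ExonState, ...]], column: int
) -> tuple[int, list[dict[str, ExonState]]]:
    """Score and all co-optimal Dollo labelings of one column."""
    col = {g: leaf_states[g][column] for g in tree.leaves}
    return _column_labelings(tree, col)


class GeneEventKind(enum.Enum):
    CONSTITUTIVE_GAIN = "constitutive_gain"
    ALTERNATIVE_GAIN = "alternative_gain"
    LOSS = "loss"
    STATUS_SWITCH = "status_switch"


@dataclass(frozen=True)
class GeneEvent:
    column: int
    kind: GeneEventKind


def gene_level_events(
    matrix: ExonStateMatrix, tree: GeneTree
) -> dict[tuple[str, str], list[GeneEvent]]:
    """Per-edge gene-level exon events, from parent/child state comparison.

    Constitutive gains and losses make the corresponding column change free at
    the transcript level on that edge; alternative gains and status switches
    carry ordinary transcript-level costs.
    """
    if not matrix.is_dollo(tree):
        raise ValidationError("exon state matrix violates the Dollo property")
    events: dict[tuple[str, str], list[GeneEvent]] = {}
    for p, c in tree.edges():
        evs: list[GeneEvent] = []
        for i, (sp, sc) in enumerate(zip(matrix[p], matrix[c])):
            if sp is sc:
                continue
            if sp is ExonState.ABSENT and sc is ExonState.CONSTITUTIVE:
                evs.append(GeneEvent(i, GeneEventKind.CONSTITUTIVE_GAIN))
            elif sp is ExonState.ABSENT and sc is ExonState.ALTERNATIVE:
                evs.append(GeneEvent(i, GeneEventKind.ALTERNATIVE_GAIN))
            elif sc is ExonState.ABSENT:
                evs.append(GeneEvent(i, GeneEventKind.LOSS))
            else:
                evs.append(GeneEvent(i, GeneEventKind.STATUS_SWITCH))
        events[(p, c)] = evs
    return events


def free_columns(
    events: dict[tuple[str, str], list[GeneEvent]]
) -> dict[tuple[str, str], frozenset[int]]:
    """Columns whose transcript-level change is free on each edge."""
    free = {}
    for edge, evs in events.items():
        free[edge] = frozenset(
            e.column
            for e in evs
            if e.kind in (GeneEventKind.CONSTITUTIVE_GAIN, GeneEventKind.LOSS)
        )
    return free
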