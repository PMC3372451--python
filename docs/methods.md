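# Methods

## The two-level model

A gene family is a rooted binary gene tree; each extant gene carries a set
of observed transcripts encoded over shared (orthologous) exon columns.
Evolution happens on two levels:

1. **Gene level.**  Every exon column takes one of three states per gene —
   absent, alternative, constitutive — and evolves independently with unit
   cost for any transition.  All gene-level events are free in the final
   score; their only role is to license free transcript-level changes.
2. **Transcript level.**  Transcripts are subsets of the gene's exons (an
   integer per column; alphabets larger than {0,1} encode alternative
   3'/5'-site configurations, intron retention is an extra cassette
   column).  A transcript lineage evolves along gene-tree edges, may gain or
   lose exons (cost `c_E` per column), die (`c_D`), or spawn a new lineage
   (`c_B`).

A solution is a forest of transcript trees, each a subtree of the gene tree
(one node per gene), with score `S = c_B·N_tree + c_D·N_death + S_F`.

Assumptions worth making explicit: transcripts never alter the gene
structure; paralogous exons are distinct columns (ortholog assignment is the
caller's problem); gene duplication nodes are ordinary binary nodes; leaf
exon states are inferred purely from the observed transcripts, so an exon
that is present in the genome but spliced into no transcript is
indistinguishable from an absent one.

## Ancestral exon states (Dollo)

Per column we minimize unit-cost transitions subject to single origin: the
exon arises at one node (possibly the root) and is never re-created after a
loss.  The implementation enumerates the origin node over the ancestors of
the LCA of the present leaves and runs a no-regain downward dynamic program;
this is equivalent to filtering plain Sankoff co-optima for Dollo
consistency when such optima exist, and otherwise yields the best
single-origin relabeling directly.  All co-optimal labelings are
retrievable; the deterministic default is the lexicographically smallest
over node ids with state order absent < alternative < constitutive.  The
root has no prior.  Parent/child state comparison yields the per-edge event
lists; only constitutive gains and losses make the column's transcript-level
change free on that edge.

## Topologies

Because a transcript tree visits each gene at most once and every tree node
at an internal gene keeps at least one child (a slot dying on both edges
explains nothing and only adds cost), a tree is fully described by its root
gene and the set of leaf genes it reaches; its node set is the union of the
root-to-leaf paths.  A topology is a multiset of such shapes whose per-leaf
coverage equals the observed transcript counts.  The sorted shape multiset
is the canonical key: slots within a gene are interchangeable.  A topology
is valid when every gene hosts a slot and the gene graph whose edges are
spanned by at least one tree is connected (a newborn-only gene with no
spanned incident edge is unconnected and rejected — the model insists that
all genes be linked).

`remove_edge` (cut a link: the subtree becomes a new tree, the remnant gains
a death) and `branch_swap` (exchange the subtrees below the same gene edge
between two trees) are the classic moves over this space.  Their closure
does not generate every forest, however: both moves conserve the total slot
count, while valid forests with the same tree count can differ in slots
(on a two-transcript cherry, {A(D,E), A(D,-), A(-,E)} has seven slots and no
merge partner).  Enumeration therefore generates each tree-count level
directly by backtracking over shapes with demand pruning, which is complete
by construction and emits levels in canonical-key order; the edit moves
remain available as operations.  We do not cap slots per ancestral gene
beyond what leaf demand implies — a fixed per-gene cap would exclude valid
forests such as two sibling-covering trees meeting at their parent.

## Leaf assignment

Given a topology, a *state* of a gene is its ordered slot list with
pointers into one state of each child; the guide tree groups slots by
identical subtree shape and restricts pointers to shape-matching child
slots.  Without that constraint a gene with `k_LR` two-child slots, `k_L`
left-only and `k_R` right-only slots over `n`-slot child states admits up to
`C(n,k_LR)·n!/(n−k_LR)!·C(n−k_LR,k_L)·C(n−k_LR,k_R)` states; the boxes
usually cut this drastically.

The dynamic program runs postorder.  An entry is indexed by (state, root
scenario), the scenario being the set of slots left unpointed by the parent
(their shape multiset is fixed by the topology; only the choice of
representatives varies).  An entry's value is the minimum over child states
of the children's entry values plus the Sankoff scores (minMP) of the
scenario's root slots, whose exon profiles are combined from the pointed
child profiles with the per-edge free-column modification and an infinity
mask where the gene lacks the exon.  Each entry commits the profiles of its
first-found optimal child pair for consumption one level up; ties are all
retained for backtracking.  Inside `assign_leaves` leaf genes keep the
identity ordering only — parent pointer injections already range over all
matchings, so the k! leaf states of the public `enumerate_states` contract
would be redundant there.

This procedure is exhaustive for gene trees of depth ≤ 2 (the level below a
node is jointly optimized with the node's own root scores; deeper choices
are committed) and heuristic above.  Two consequences: first, deeper-level
commitments can be suboptimal for upstream profiles — measured in the
benchmark; second, tied chains can re-score differently, so every
backtracked chain is re-scored exactly by per-tree Sankoff on the assembled
forest and only the exact minimum among them is returned, which keeps all
returned solutions at exactly equal scores.

## Search

Topologies are explored by increasing tree count.  The lower bound of a
topology is `c_B·N_tree + c_D·N_death` plus, per tree, its best parsimony
as if all transcripts were available (leaf slots may pick any observed
configuration of their gene, trees do not compete) — a true bound, computed
once per shape and cached.  The same per-shape bound prunes level
enumeration itself: a partial forest whose summed shape bounds exceed the
incumbent cannot complete into anything competitive.  The incumbent starts
from seeded random sampling (uniform tree memberships per leaf slot, uniform
root placement, random leaf assignment — every sample is a feasible
solution, hence an upper bound).  The search stops when `c_B·t` alone
exceeds the incumbent; tree counts are bounded by the total transcript count
regardless.  Topologies whose bound equals the incumbent are still refined
so that every co-optimal solution is found.

Co-optimal solutions are ranked by total event count (transcript-level
column changes, free or not, plus births, deaths and gene-level events) and
then by decreasing mean similarity index — per tree, the sum over leaves of
that leaf's exons shared with at least one other leaf, divided by the number
of exons in any leaf times the number of leaves (1 if the tree has no
included exon).

**Extended model.**  After leaf assignment, each tree's birth cost becomes
the `c_E`-weighted Hamming distance of its root vector to the closest
transcript vector among earlier-created trees at the same gene or above
(trees ordered by root depth, then canonically; the first tree falls back to
the constant `c_B`).  No useful lower bound exists on such births, so the
extended search enumerates every topology; it is gated behind an option and
an instance-size guard (12 transcripts by default).  Among co-optimal
assignments only those of minimum total birth cost are kept.

## Simulator

`simulate` evolves, from `n_E` exons and `n_T` transcripts at the root,
every gene-tree edge: absent exons are born (uniformly alternative or
constitutive), present ones die; surviving transcripts inherit, are forced
to follow constitutive gains and losses (free, as in the scoring model),
flip alternative columns with the gain/loss rates, die, or spawn a copy with
one random flip.  Extinct nodes are repaired by reviving a random parent
lineage (logged and flagged).  Defaults are 100 exons, ancestral transcript
count uniform on {1..4} when unset, and 0.05 per edge per exon/transcript
for every event — a sparse-event regime with visible signal and occasional
noise.  The generator permits repeated exon origins (it is not
Dollo-constrained); violating columns are flagged so the reconstructor is
tested on both regimes.  The ground truth records lineage parentage and
event counts, so the generating history's cost is available as an upper
bound on the optimum.

## Brute-force oracle and benchmark

The oracle enumerates every transcript assignment of a topology (guarded at
10^6) with per-tree score tables, and over all topologies uses a forest
constructor independent of the search's enumerator: restricted-growth
partitions of the leaf slots into trees followed by explicit root placement.
Its pruning uses only true bounds (structural part plus the relaxed per-tree
score; elevating a root only adds edges and deaths), so it remains exact.

`benchmark_optimality` sweeps caterpillar trees — every internal node has a
leaf child, maximal depth per leaf count, the hardest shape — and reports,
per topology, whether the heuristic assignment hits the exhaustive optimum
and by how much it misses, plus the share of the structural topology space
the pruned search actually refines.  When a run's space exceeds the
per-run cap the comparison uses a seeded cluster sample (whole partitions at
a time); the space size itself is computed exactly by a closed-form count.

## Problem sizes and defaults used by the test suite

The suite validates oracle equivalence on 100 instances with ≤ 3 leaves and
≤ 3 transcripts per gene and on 100 single-transcript instances with up to 8
leaves (20 exons each), bound soundness on 200 instances (10 exons), and the
benchmark trends on 100 runs per grid point with 10-exon genes, the leaf
sweep 3–6 at one ancestral transcript and the transcript sweep at four
leaves with up to two — sizes chosen so the exhaustive oracle stays within
its guard while the qualitative trends (optimality falling with depth and
transcript load, the refined fraction shrinking, the score gap growing but
staying small) are clearly expressed.

## Known limitations

* The leaf assignment is exact only to depth two; above that it is the
  measured heuristic, and the solution *set* (not just the score) may be
  incomplete on deep trees.
* Everything is exponential in the worst case; the tool targets single gene
  families at curated scale, not genome-wide scans.
* The simulator emulates presence/absence evolution only — no sequence
  evolution, no rate heterogeneity across exons, no correlated splicing
  events — so passing tests support algorithmic correctness, not the
  biological fidelity of the model itself.
* Ancestral-state ties are resolved to one deterministic matrix by default;
  downstream solution sets can differ under other co-optimal matrices (they
  are all retrievable).
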