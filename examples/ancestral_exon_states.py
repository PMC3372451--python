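"""Reconstruct ancestral gene structures under Dollo parsimony.

Exon columns evolve over {absent, alternative, constitutive} with unit-cost
transitions, but an exon may be created only once on the whole tree.  The
per-column dynamic program returns every co-optimal labeling; the events
derived from the chosen labeling decide which transcript-level changes are
free during scoring.
"""

from spliceforest import (
    ExonState,
    GeneTree,
    Transcript,
    gene_level_events,
    leaf_exon_states,
    reconstruct_ancestral_exon_states,
)

tree = GeneTree.from_newick("((human,mouse)hm,fish)root;")
transcripts = {
    "human": [
        Transcript("h1", "human", (1, 1, 0)),
        Transcript("h2", "human", (1, 0, 0)),
    ],
    "mouse": [
        Transcript("m1", "mouse", (1, 1, 0)),
    ],
    "fish": [
        Transcript("f1", "fish", (1, 0, 1)),
        Transcript("f2", "fish", (1, 1, 1)),
    ],
}

rows = leaf_exon_states(transcripts, 3)
matrix = reconstruct_ancestral_exon_states(tree, rows)
print("gene".ljust(8), "e1  e2  e3")
for node in tree.postorder():
    states = "  ".join(s.value.ljust(2) for s in matrix[node])
    print(node.ljust(8), states)

events = gene_level_events(matrix, tree)
print("\ngene-level events:")
for edge, evs in events.items():
    for e in evs:
        print(f"  {edge[0]} -> {edge[1]}: column {e.column + 1} {e.kind.value}")

# e1 is constitutive throughout; e2 is alternative wherever present; e3 is
# private to fish, so Dollo places a single origin on the fish branch (or a
# root presence lost in the other clade, whichever needs fewer transitions).
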