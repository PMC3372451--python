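# spliceforest

Parsimony reconstruction of the evolutionary history of alternatively
spliced transcripts on a known gene tree.

## The problem

Alternative splicing lets one gene produce several transcripts (isoforms) by
including or skipping exons.  While exon and intron evolution is well
studied, the transcripts themselves also evolve: isoforms are gained, lost
and modified along a gene family's history.  `spliceforest` reconstructs
that history for people studying isoform evolution in a gene family: given a
rooted binary gene tree and, for each extant gene, its transcripts encoded
as integer vectors over orthologous exon columns (0 = exon excluded, k ≥ 1 =
included in configuration k), it returns every most-parsimonious *forest of
transcript trees* explaining the observations.

## The model

Evolution is two-level.  The gene structure evolves first: each exon column
is **absent**, **alternative** or **constitutive** in each gene, ancestral
states are reconstructed by small parsimony (unit transition costs) under a
Dollo constraint — an exon cannot be created twice.  Gene-level events are
free.  On top of it, transcripts evolve as subsets of the current gene
structure; a solution is a forest in which every transcript tree is a
subtree of the gene tree, scored by

    S = c_B · N_tree + c_D · N_death + S_F

where `N_tree` counts transcript births (each tree root), `N_death` counts
transcript losses (missing children at internal genes), and `S_F` is the sum
of the Sankoff parsimony scores of the trees: a transcript-level exon
gain/loss costs `c_E` — except on an edge where the gene itself gained the
exon as constitutive or lost it, which is free.  `c_E = inf` restricts
solutions to forests whose trees never flip an exon at the transcript level.

The search enumerates topologies (forests with unassigned leaves) with
increasing tree counts, prunes them with a true lower bound, finds the best
leaf assignments through a guide-tree-constrained dynamic program, and
returns all solutions of minimum cost ranked by event count and a leaf
similarity index.  An extended model replaces the constant birth cost by the
change distance of each newborn to its closest ancestor transcript.

## A worked example

`examples/infer_transcript_phylogeny.py` builds a two-gene family in which
each gene has a long and a short isoform and gene E gained exon `e3`
constitutively:

```
minimum score: 2.0
co-optimal solutions: 1
trees: 2, deaths: 0, S_F: 0.0
  (D.long,E.long)A   similarity index 0.67
  (D.short,E.short)A   similarity index 0.50
```

The optimum costs exactly two transcript births — the two ancestral
isoforms.  Both trees have zero parsimony cost even though the long isoforms
differ by `e3`: that difference is explained by the free constitutive gain
at the gene level, not by a transcript-level event.  The other examples
simulate evolution forward and recover it (`simulate_and_recover.py`) and
show the Dollo reconstruction of ancestral gene structures
(`ancestral_exon_states.py`).

## Command line

```sh
spliceforest infer --gene-tree family.nwk --transcripts family.tsv \
    --cb 1 --cd 1 --ce 1 --seed 0 --out result.json
spliceforest simulate --leaves 5 --seed 7 --out-prefix sim
spliceforest benchmark --runs 20 --leaves 3 --leaves 4 --seed 0 --out bench.csv
```

The transcript matrix is TSV with columns `transcript_id`, `gene_id`, then
one integer per exon column (header `name[:m]` widens the alphabet for
alternative 3'/5' sites).  Exit codes: 2 for input errors, 3 when no finite
solution exists (possible with `--ce inf`).

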