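# mtpaleo

Structural paleogenomics for plant mitochondrial genomes.

Plant mt genomes keep a nearly constant gene repertoire while their
*architecture* churns: repeated sequences recombine, reversing blocks of
genes, duplicating regions, and gaining or losing individual genes.
Because mitochondria are maternally inherited, those structural states are
clean markers of maternal ancestry — in hybrid crop complexes such as the
*Brassica* allotetraploids, the mt genome identifies which parent was the
mother.  `mtpaleo` is a toolkit for this kind of analysis: it turns
annotated circular genomes into signed gene orders, finds the basic
syntenic blocks shared across taxa, counts the minimum structural events
separating any two genomes, reconstructs ancestral genome arrangements on
a rooted phylogeny, and tests whether repeats sit at block boundaries.

## The model

Each genome is reduced to a **signed gene order** — the genes around the
circle with their coding strands — anchored at *rrn5* (exon clusters of
trans-spliced genes count as independent tokens).  A **basic syntenic
block** is a maximal run of genes whose order and relative orientation is
conserved, possibly as a reversed unit, in every genome that contains
them; each genome then becomes a short signed permutation of block ids.

For two arrangements π and σ with the same blocks, the minimum number of
reversals is computed exactly from the breakpoint graph
(Hannenhalli–Pevzner):

    d(π, σ) = (n + 1) − c + h + f

with *c* the number of graph cycles, *h* the hurdles and *f* the fortress
indicator.  Content differences add one step per event: a block private to
one genome is a gene gain or loss; a repeated occurrence run of duplicated
blocks collapses as a single block duplication.  The total — the
**structural distance** — is symmetric, and an explicit optimal event
scenario is produced alongside it.

Ancestral arrangements on a rooted tree follow collinearity rules: if a
descendant of a node is collinear (distance zero on shared blocks) with
the node's outside context, or if the earliest-diverging child clade is
collinear with another child clade, that shared arrangement is ancestral;
remaining nodes take the most parsimonious descendant arrangement and are
flagged.  Block presence at internal nodes follows Dollo parsimony (gained
once, lost freely), and events are then read off branch by branch.

A seeded simulator generates ground-truth histories — reversions, gains,
losses, tandem duplications on a tree, optionally with nucleotide
sequences carrying inverted repeats planted at reversion breakpoints — so
every stage of the pipeline is testable end to end without downloads.

## Worked example

```python
from mtpaleo import (SimulationConfig, simulate_history, canonicalize,
                     identify_blocks, reconstruct_ancestors,
                     infer_branch_events)

history = simulate_history(SimulationConfig(seed=11, mean_events_per_branch=1.5))
orders = [canonicalize(o) for o in history.leaf_orders.values()]
catalog, seqs = identify_blocks(orders, reference="OG")
states = reconstruct_ancestors(history.phylogeny, seqs)
summary = infer_branch_events(history.phylogeny, states)
print(len(catalog), summary.totals, summary.grand_total)
```

Running the same steps via `examples/02_syntenic_blocks.py` and
`examples/04_ancestral_reconstruction.py` prints (abridged):

```
8 basic blocks across 7 taxa (events simulated: 4)
  OG   +1 +2 +3 +4 +5 +6 +7
  T2   +1 +2 -3 +4 +5 +6 -7
  T5   +1 +8 +2 +3 +4 -5 +6 +7
...
events by kind: {'reversion': 2, 'gene_gain': 2, 'gene_loss': 1, 'block_duplication': 0}
grand total: 5 (simulated truth: 5)
cumulative steps from the common ancestor to each taxon:
  T2   3
  T4   1
```

Read: the seven genomes decompose into 8 shared blocks; T2's genome
differs from the ancestor by flipped blocks 3 and 7; five structural
events are inferred on the tree and they match the simulated truth
exactly; the cumulative row is the number of changes each extant genome
has accumulated since the common ancestor.  The repeat example
(`examples/05_repeats_and_boundaries.py`) ends with

```
boundary association in T2: 26 of 26 occurrences within 1 kb of a block boundary
(null mean 9.6, permutation p = 0.0001)
```

— every repeat sits at a block boundary, far more than the rotational
null expects, the signature of repeat-mediated reversions.

Each example in `examples/` is a short narrative script for one
capability; a thin CLI (`mtpaleo extract | blocks | distance | ancestors |
repeats | simulate`) exposes the same pipeline on files, including real
GenBank accessions.

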