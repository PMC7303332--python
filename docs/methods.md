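# Methods

## Scope and data model

The toolkit analyses the *structure* of circular organellar genomes, not
their sequences' substitutions.  A genome enters the pipeline as an
annotated GenBank record and is reduced to a signed gene order: tokens
`(symbol, exon_part, copy_index, sign)` ordered by start coordinate, with
0-based half-open coordinates internally (GenBank's 1-based inclusive
intervals are converted at the parsing boundary, which keeps arithmetic
across the origin unambiguous).  Pseudogenes are parsed and retained on
the `AnnotatedGenome` but excluded from gene orders by default — for
structural comparison a non-functional gene is a gap.  Unnamed `orfNNN`
features are dropped by default as well, since taxon-specific ORFs would
otherwise inflate the block catalog with meaningless singletons.

Trans-spliced genes: the segments of one gene are grouped into exon
clusters, splitting wherever another gene's segment starts inside a gap.
Each cluster becomes its own order token (`nad1_p1`, `nad1_p2`, ...),
because clusters at distant loci rearrange independently.  Cis-spliced
exons with no intervening gene stay one token.

Nomenclature is unified before comparison: tRNA spellings
(`trnY-GUA`, `trnY (GUA)`, ...) fold to `trnY(GUA)`; gene-family names
(nad/cox/atp/rps/rpl/rrn/...) are case-folded with the conventional
mixed-case exceptions (`matR`, `mttB`, `ccmB/C/Fc/Fn`); an explicit
synonym table can override or extend these rules.  Unmapped names pass
through and are logged.  Copies of one symbol get `copy_index` in
coordinate order.

Circular orders are canonicalized by rotating the anchor gene (`rrn5` by
default) to the front; if the anchor lies on the minus strand the whole
order is first reflected (reversed, all signs flipped), so the two
strand-readings of one molecule canonicalize identically.  The operation
is idempotent and preserves the adjacency structure of the circle.

## Basic syntenic blocks

An adjacency (x→y) between signed genes is **conserved** when

1. x and y occur in exactly the same set of taxa, and
2. in every order, *every* occurrence of x and of y respects the
   adjacency, allowing the reflected form (−y→−x).

Rule 1 makes gene content differences visible: a gene absent from one
taxon cannot hide inside a larger block, so every gained or lost gene
surfaces as a single-gene block, which is what lets gains and losses be
counted at block level.  Rule 2 handles duplications: the interior
adjacencies of a tandem-duplicated run hold in every copy and survive,
while the run's boundary adjacencies differ between copies and split — a
duplicated region therefore appears as one block occurring twice, flagged
on the `BlockSequence`.

Blocks are the maximal chains of conserved adjacencies (genes are chained
end-to-end; conflicting chain joins are dropped with a log message); a
chain that closes into a cycle is a wholly conserved circular genome and
is cut at the reference taxon's first token.  Blocks are numbered by first
appearance in a designated reference taxon, making the catalog
deterministic under permutations of the input list.  Projection of a
taxon onto the catalog is gap-tolerant: a block's gene list is matched
after restriction to the genes the taxon actually has, so an
annotation-level missing gene does not break the block.

Adding a taxon can only split blocks or leave them unchanged (adding
constraints never merges chains); this fusion monotonicity is asserted in
the tests.

## Structural distance

For same-content arrangements the reversal distance is the exact
Hannenhalli–Pevzner value `d = (n+1) − c + h + f` on the breakpoint graph
of the signed permutation.  Orientation of a gray edge is read off the
parity of its endpoint positions; hurdles are the unoriented components
whose positions form one contiguous arc on the circle of graph positions
(i.e. they do not separate other unoriented components); a fortress is an
odd number of hurdles, all superhurdles.  The implementation is certified
against breadth-first search: exhaustively for all signed permutations up
to 7 elements during development, and in the test-suite exhaustively at 3
elements plus 500 random cases per size for 4–8 elements.
`reversal_distance_bfs` (meet-in-the-middle, refused above 10 blocks)
remains available as the independent oracle, and
`reversal_distance_table` materializes whole distance spheres (n ≤ 8) by
vectorized breadth-first search.

An explicit optimal scenario is produced by greedy descent on the exact
distance: at each step the first distance-reducing reversal, ordering
candidates by left endpoint and then span length.  Optimality of the
scenario length is inherited from the distance function; the ordering rule
makes scenarios reproducible.

Content differences are charged one step per event, every kind costing 1:

* a block id private to the target is a **gene gain** (all its
  occurrences inserted in one step); private to the source, a
  **gene loss**;
* ids with more occurrences on one side collapse to the other side's copy
  number.  Which copies to delete is chosen by a bounded exhaustive
  search (≤ 64 combinations, context-scored greedy beyond) minimizing the
  number of contiguous deletion runs plus the residual reversal distance —
  so a duplication whose copies were later separated by reversions still
  counts as the single event it was.  Each contiguous deletion run is one
  **block duplication** step, in either direction of comparison;
* ids duplicated equally on both sides are matched copy-to-copy by the
  assignment (≤ 64 permutations) minimizing the reversal distance.

Circular arrangements are reduced to the linear problem by pinning the
smallest single-copy shared block at the front (rotating/reflecting both
sides); a reversal scenario on a circle never needs to cross a fixed
anchor.  The resulting structural distance is symmetric by construction,
and on histories simulated with non-overlapping events it equals the
number of events exactly; with overlapping events it can only undercount
(a minimum is a lower bound on any particular event sequence) — both
properties are asserted over hundreds of seeded replicates.

One naming caveat: a *decrease* in copy number between two genomes is
reported as a `block_duplication` step (the collapse of the duplicated
run), not as a loss, so that the same pair gives the same event list in
both directions.  In rooted, forward-time branch scenarios duplications
always expand, so per-kind branch tallies are unaffected.

## Ancestral reconstruction

Given one arrangement per leaf and a rooted tree with a designated
outgroup, internal ingroup nodes are inferred in post-order:

* **case 1** — if a descendant leaf is collinear (structural distance 0 on
  shared blocks) with the node's context (the sibling state when already
  available, else the outgroup arrangement), that arrangement is
  ancestral;
* **case 2** — else, if a leaf of the earliest-diverging child clade is
  collinear with a leaf of another child clade, the shared arrangement is
  ancestral; both members of the collinear pair are candidate
  representatives;
* **fallback** — else the descendant-leaf arrangement minimizing the
  summed structural distance to the child states and the context is
  chosen and flagged `parsimony_fallback`; exact ties with distinct
  arrangements are flagged `ambiguous` with all candidates listed, and
  event inference refuses to proceed until resolved (or explicitly
  allowed to take the first candidate).

Among collinear candidates the one covering most of the node's block
content is preferred: collinearity is judged on shared blocks, and a leaf
that lost a block can be collinear while unable to represent the full
ancestral content.  Content itself is set by Dollo parsimony — a block is
present at a node iff it is seen in at least two directions (child
subtrees, or the outside of the node) — so each gain lands on the stem of
the clade where the block first appears and losses are assigned below.
The chosen leaf arrangement is restricted to that content.  No state is
inferred above the outgroup split; the ingroup-root state stands for the
common ancestor, and the outgroup branch carries no events.

Branch scenarios are the structural distances parent→child; the summary
aggregates per-kind totals, the grand total, and cumulative step counts
from the root to each extant taxon.

## The simulator

`simulate_history` evolves a root of `n_blocks` blocks (default 15, block
1 carrying the `rrn5` anchor on the plus strand; 1–5 genes per block from
a plant-mt-like vocabulary) along a rooted tree (default six ingroup
leaves and an outgroup) by reversions, gene gains, gene losses and tandem
block duplications.  Events per branch are Poisson(`mean_events_per_branch`,
default 1.0); kinds are drawn with weights 17:4:4:1
(reversions dominating, duplications rare), the mix characteristic of
crucifer mt evolution.  All randomness flows from one mandatory seed;
repeated runs are byte-identical.

In **non-overlap** mode (the default) an event's blocks plus one flank
are reserved globally — no span is reused anywhere in the tree — and each
internal node keeps an event-free line of descent to at least one leaf
(one child per node inherits the state unchanged).  Under these
conditions the true history is uniquely recoverable, and the pipeline's
exact recovery of every ancestral state and per-branch event count over
hundreds of seeded histories is an acceptance criterion.  Unplaceable
events under the reservation rule are dropped with a log message; the
recorded ground truth always reflects the events actually applied.
**Free** mode lifts the constraints for stress testing; there the
guarantee weakens to the undercount bound described above.

When sequences are requested, each gene receives a fixed random sequence
(200–900 bp) shared across taxa; intergenic junctions receive per-leaf
random spacers (default 2 kb — plant mt genomes are mostly intergenic,
and this keeps that character at test-friendly scale, ~50–120 kb per
genome); and each reversion on a leaf's history plants one fresh repeat
sequence (default 200 bp) as an inverted pair at the two block junctions
the reversion created.  Leaves sharing an event share its repeat
sequence, so cross-taxon family clustering is exercised.  The emitted toy
GenBank records round-trip exactly through the parser.  What the
simulator does *not* model: nucleotide substitutions, indels, annotation
errors beyond naming variants, nested/partial gene copies, or
substoichiometric isoforms — so passing recovery tests demonstrate the
pipeline's correctness on clean structural signal, not robustness to
annotation noise in real records.

## Repeats

`find_repeats` reports all maximal exact repeated pairs (direct and
inverted, `N` never matching) of length ≥ `min_len` (default 50 bp;
values below 8 are refused as an output-explosion guard), with circular
wrap.  The implementation seeds on `min_len`-mers and extends each
candidate pair maximally in both directions on the circle, deduplicating
on the maximal coordinates; the contract is agreement with an independent
quadratic scan (every offset for direct pairs, every anti-diagonal for
inverted ones), asserted on 50 random 2-kb circular sequences with
planted pairs, together with per-pair maximality.

Families are single-linkage clusters of repeat occurrences across taxa at
≥ 90% identity over the shorter sequence (edlib infix alignment, best of
the two orientations), ordered by total member length.

Boundary association is a rotation permutation test: the observed count
of repeat occurrences whose interval comes within `window` (default
1 kb; 0.5/1/2 kb reported by the CLI) of a block boundary is compared to
`n_perm` (default 9999) independent uniform rotations of each occurrence
around the circle, with `p = (1 + #{null ≥ observed}) / (1 + n_perm)` —
never zero, reproducible bit-for-bit given a seed.

## Numerical and scale choices

Problem sizes in the test-suite and acceptance script are chosen to
exercise the mathematics at full strength while completing in minutes on
one CPU: exhaustive reversal-distance verification to 7 blocks during
development and randomized certification at 4–8 blocks in the suite (real
mt arrangements have ~15 blocks, well within the formula's validity — the
formula is exact at any size; only the BFS oracle is size-limited);
200-replicate recovery runs; 2-kb sequences for the quadratic repeat
oracle; ~50–90 kb simulated genomes elsewhere.  The bounded searches in
duplication handling (64-combination caps) fall back to deterministic
greedy choices beyond the cap; real datasets with more than a handful of
duplicated blocks per genome would be the place to revisit them.

## Known limitations

* Ancestral states are always drawn from observed leaf arrangements;
  an ancestor unlike every extant genome (possible under dense,
  overlapping histories) cannot be proposed, only approximated and
  flagged.  This mirrors the collinearity method's own logic.
* Translocations are expressed as compositions of reversions; no separate
  translocation operator exists, and no DCJ or block-interchange distance
  is provided.
* Repeat finding is exact-match only; diverged repeat copies are joined
  at the family-clustering stage (identity threshold), not during pair
  finding.
* The equal-copy matching and collapse searches are exact only within
  their combinatorial caps.
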