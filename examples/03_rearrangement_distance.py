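"""Minimum structural steps between two genomes, with the event scenario.

The distance charges one step per event: a signed reversal (computed
exactly via the breakpoint graph), a gene gain or loss (a block private to
one genome), or a block duplication (a repeated occurrence run collapsing
to one copy).  The scenario lists one optimal event sequence.
"""

from mtpaleo import (
    SimulationConfig,
    canonicalize,
    identify_blocks,
    pairwise_matrix,
    simulate_history,
    structural_distance,
)

history = simulate_history(
    SimulationConfig(seed=11, mean_events_per_branch=1.5)
)
orders = [canonicalize(o) for o in history.leaf_orders.values()]
catalog, seqs = identify_blocks(orders, reference="OG")
by_tax = {s.taxon_id: s for s in seqs}

d, scenario = structural_distance(by_tax["OG"], by_tax["T4"])
print(f"OG -> T4: {d} steps")
for e in scenario.events:
    print(f"  {e.kind:18s} span={e.span}")

matrix = pairwise_matrix(seqs)
print("\npairwise structural steps:")
print(matrix.to_frame().to_string())
print("\nThe matrix is symmetric with a zero diagonal; each entry is the "
      "minimum\nnumber of reversions + gains + losses + duplications "
      "separating two genomes.")
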