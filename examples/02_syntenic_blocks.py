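"""Identify basic syntenic blocks shared across taxa.

A basic syntenic block is a maximal run of genes whose order and relative
orientation is conserved (possibly as a reversed unit) in every genome
containing them.  Re-expressing each genome as a signed block arrangement
reduces whole-genome structural comparison to a short signed sequence.
"""

from mtpaleo import SimulationConfig, canonicalize, identify_blocks, simulate_history

history = simulate_history(SimulationConfig(seed=11))
orders = [canonicalize(o) for o in history.leaf_orders.values()]
catalog, arrangements = identify_blocks(orders, reference="OG")

print(f"{len(catalog)} basic blocks across {len(orders)} taxa "
      f"(events simulated: {history.total_events()})\n")
for block in catalog.blocks:
    genes = " ".join(
        ("+" if s > 0 else "-") + g[0] for g, s in block.genes
    )
    print(f"  block {block.block_id:2d}: {genes}")
print()
for seq in arrangements:
    arr = " ".join(f"{x:+d}" for x in seq.arrangement)
    dup = f"   (duplicated: {seq.duplicated})" if seq.duplicated else ""
    print(f"  {seq.taxon_id:4s} {arr}{dup}")
print("\nEach row is one genome as a signed block sequence; a sign flip "
      "marks\na reversed block, a repeated id a duplication.")
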