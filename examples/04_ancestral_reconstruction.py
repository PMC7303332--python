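"""Reconstruct ancestral genome arrangements on a rooted phylogeny.

Internal-node arrangements are inferred from collinearity: structure
shared between a descendant and the outside context (case 1), or across
the earliest-diverging split (case 2), predates the node; remaining nodes
fall back to the most parsimonious descendant arrangement.  Events are
then assigned to branches and tallied by kind.
"""

from mtpaleo import (
    SimulationConfig,
    canonicalize,
    identify_blocks,
    infer_branch_events,
    reconstruct_ancestors,
    simulate_history,
)

history = simulate_history(
    SimulationConfig(seed=11, mean_events_per_branch=1.5)
)
orders = [canonicalize(o) for o in history.leaf_orders.values()]
catalog, seqs = identify_blocks(orders, reference="OG")
states = reconstruct_ancestors(history.phylogeny, seqs)
summary = infer_branch_events(history.phylogeny, states)

print("inferred ancestral arrangements:")
for nid, seq in states.states.items():
    label = states.node_labels[nid]
    status = states.status[nid]
    if status == "leaf":
        continue
    arr = " ".join(f"{x:+d}" for x in seq.arrangement)
    print(f"  {label:3s} [{status}] {arr}")

print(f"\nevents by kind: {summary.totals}")
print(f"grand total: {summary.grand_total} "
      f"(simulated truth: {history.total_events()})")
print("\ncumulative steps from the common ancestor to each taxon:")
for taxon, steps in sorted(summary.cumulative_from_root.items()):
    print(f"  {taxon:4s} {steps}")
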