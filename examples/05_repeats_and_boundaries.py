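"""Exact repeats, repeat families, and their link to block boundaries.

Inverted repeats recombine and reverse the region between them, so repeats
are expected to sit at the boundaries of syntenic blocks.  The example
finds all maximal exact repeat pairs (>= 50 bp) in a simulated genome,
clusters homologous repeats across taxa, and runs a rotation permutation
test for boundary association.
"""

from mtpaleo import (
    SimulationConfig,
    boundary_enrichment,
    cluster_repeat_families,
    find_repeats,
    simulate_history,
)

history = simulate_history(
    SimulationConfig(seed=5, emit_sequences=True, non_overlap=False,
                     mean_events_per_branch=3.0, kind_weights=(1, 0, 0, 0),
                     spacer_length=4000)
)
pairs = {}
for taxon, seq in history.sequences.items():
    pairs[taxon] = find_repeats(seq, min_len=50, circular=True,
                                taxon_id=taxon)
    if pairs[taxon]:
        print(f"{taxon}: {len(pairs[taxon])} repeat pairs, longest "
              f"{max(p.length for p in pairs[taxon])} bp")

families = cluster_repeat_families(pairs, history.sequences)
print(f"\n{len(families)} repeat families across taxa "
      f"(largest spans {len(families[0].members)} occurrences)")

taxon = max(pairs, key=lambda t: len(pairs[t]))
seq = history.sequences[taxon]
result = boundary_enrichment(pairs[taxon], history.block_junctions[taxon],
                             len(seq), window=1000, n_perm=9999, seed=1)
print(f"\nboundary association in {taxon}: {result.observed} of "
      f"{2 * len(pairs[taxon])} occurrences within 1 kb of a block "
      f"boundary\n(null mean {result.null_mean:.1f}, permutation "
      f"p = {result.p_value:.4f})")
print("\nA small p confirms repeats concentrate at block boundaries — the "
      "signature\nof repeat-mediated reversions.")
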