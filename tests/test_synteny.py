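"""Conserved adjacencies, block identification, expansion, coordinates."""

from __future__ import annotations

import numpy as np
import pytest

from mtpaleo.genome_io import GeneOrder, GeneToken, canonicalize
from mtpaleo.synteny import (
    SyntenyError,
    block_coordinates,
    conserved_adjacencies,
    expand,
    identify_blocks,
    project_order,
)


def order(tax, spec, circular=True):
    """Build a GeneOrder from "+a -b" style strings."""
    toks = []
    counts = {}
    for item in spec.split():
        sign = -1 if item[0] == "-" else 1
        sym = item.lstrip("+-")
        counts[sym] = counts.get(sym, 0) + 1
        toks.append(GeneToken(sym, copy_index=counts[sym], sign=sign))
    return GeneOrder(tax, toks, circular)


def gene(sym, sign=1):
    return ((sym, 0), sign)


class TestConservedAdjacencies:
    def test_orientation_conflict_drops_pair(self):
        # c flips between taxa, so only a->b survives (linear orders keep
        # the example free of wrap-around adjacencies)
        t1 = order("T1", "+a +b +c", circular=False)
        t2 = order("T2", "+a +b -c", circular=False)
        adj = conserved_adjacencies([t1, t2])
        assert adj == {(gene("a"), gene("b"))}

    def test_identical_orders_conserve_everything(self):
        t1 = order("T1", "+a +b -c +d", circular=False)
        t2 = order("T2", "+a +b -c +d", circular=False)
        assert len(conserved_adjacencies([t1, t2])) == 3

    def test_disjoint_gene_sets_empty(self):
        t1 = order("T1", "+a +b", circular=False)
        t2 = order("T2", "+c +d", circular=False)
        assert conserved_adjacencies([t1, t2]) == set()

    def test_reflected_adjacency_counts(self):
        # (x -> y) matches (-y -> -x) in a reflected taxon
        t1 = order("T1", "+a +b", circular=False)
        t2 = order("T2", "-b -a", circular=False)
        assert conserved_adjacencies([t1, t2]) == {(gene("a"), gene("b"))}


class TestIdentifyBlocks:
    def test_internal_reversal_splits(self):
        t1 = order("T1", "+a +b +c +d +e", circular=False)
        t2 = order("T2", "+a +b -d -c +e", circular=False)
        catalog, seqs = identify_blocks([t1, t2], reference="T1")
        assert len(catalog) == 3
        assert [b.genes for b in catalog.blocks] == [
            (gene("a"), gene("b")), (gene("c"), gene("d")), (gene("e"),)
        ]
        by_tax = {s.taxon_id: s for s in seqs}
        assert by_tax["T1"].arrangement == [1, 2, 3]
        assert by_tax["T2"].arrangement == [1, -2, 3]

    def test_all_identical_single_block(self):
        t1 = order("T1", "+a +b +c")
        t2 = order("T2", "+a +b +c")
        catalog, seqs = identify_blocks([t1, t2], reference="T1")
        assert len(catalog) == 1
        assert all(s.arrangement in ([1], [-1]) for s in seqs)

    def test_numbering_fixed_by_reference_not_input_order(self):
        t1 = order("T1", "+a +b +c +d +e", circular=False)
        t2 = order("T2", "+a +b -d -c +e", circular=False)
        cat_a, _ = identify_blocks([t1, t2], reference="T1")
        cat_b, _ = identify_blocks([t2, t1], reference="T1")
        assert [b.genes for b in cat_a.blocks] == [b.genes for b in cat_b.blocks]

    def test_fusion_monotonicity(self):
        # adding a taxon can split blocks or leave them, never merge
        t1 = order("T1", "+a +b +c +d", circular=False)
        t2 = order("T2", "+a +b +c +d", circular=False)
        t3 = order("T3", "+a +b -d -c", circular=False)
        cat2, _ = identify_blocks([t1, t2], reference="T1")
        cat3, _ = identify_blocks([t1, t2, t3], reference="T1")
        assert len(cat3) >= len(cat2)
        blocks2 = [set(g for g, _ in b.genes) for b in cat2.blocks]
        blocks3 = [set(g for g, _ in b.genes) for b in cat3.blocks]
        for b3 in blocks3:
            assert any(b3 <= b2 for b2 in blocks2)

    def test_duplicated_run_listed_twice_and_flagged(self):
        t1 = order("T1", "+a +b +c +d +a +b +c +e")
        t2 = order("T2", "+a +b +c +d +e")
        catalog, seqs = identify_blocks([t1, t2], reference="T2")
        s1 = next(s for s in seqs if s.taxon_id == "T1")
        dup_ids = [bid for bid in s1.duplicated]
        assert dup_ids, "duplicated block occurrence must be flagged"
        run_block = catalog[dup_ids[0]]
        assert [g for g, _ in run_block.genes] == [("a", 0), ("b", 0),
                                                   ("c", 0)]

    def test_missing_reference_error(self):
        t1 = order("T1", "+a +b")
        with pytest.raises(SyntenyError):
            identify_blocks([t1, t1], reference="nope")

    def test_segment_count_matches_planted_breakpoints(self):
        # reversions only, non-overlapping: every reversion cuts the root
        # circle at its two ends, so the root decomposes into exactly
        # 2 * (number of reversions) segments
        from mtpaleo.simulate import SimulationConfig, simulate_history

        h = simulate_history(
            SimulationConfig(seed=9, kind_weights=(1, 0, 0, 0))
        )
        n_rev = h.total_events()
        assert n_rev >= 1
        orders = [canonicalize(o) for o in h.leaf_orders.values()]
        catalog, seqs = identify_blocks(orders, reference="OG")
        og = next(s for s in seqs if s.taxon_id == "OG")
        assert len(og.arrangement) == 2 * n_rev


class TestExpand:
    def test_spec_reversal_example(self):
        t1 = order("T1", "+a +b +c +d +e", circular=False)
        t2 = order("T2", "+a +b -d -c +e", circular=False)
        catalog, seqs = identify_blocks([t1, t2], reference="T1")
        s2 = next(s for s in seqs if s.taxon_id == "T2")
        out = expand(s2, catalog)
        assert [str(t) for t in out.tokens] == ["+a", "+b", "-d", "-c", "+e"]

    def test_unknown_block_error(self):
        from mtpaleo.synteny import Block, BlockCatalog, BlockSequence

        cat = BlockCatalog([Block(1, (gene("a"),))], reference_taxon="x")
        with pytest.raises(SyntenyError):
            expand(BlockSequence("x", [1, 2], circular=False), cat)

    def test_expand_project_roundtrip_simulated(self, default_history):
        orders = {
            o.taxon_id: canonicalize(o)
            for o in default_history.leaf_orders.values()
        }
        catalog, seqs = identify_blocks(list(orders.values()), "OG")
        for s in seqs:
            out = expand(s, catalog)
            kept = [
                (t.gene, t.sign)
                for t in orders[s.taxon_id].tokens
                if t.gene in catalog.gene_to_block()
            ]
            got = [(t.gene, t.sign) for t in out.tokens]
            # projection may rotate a circular order to a block start
            rotations = [
                kept[r:] + kept[:r] for r in range(max(1, len(kept)))
            ]
            assert got in rotations


class TestBlockCoordinates:
    def _toy(self, tmp_path, features, length=2000, circular=True):
        from conftest import make_genbank, random_dna

        seq = random_dna(np.random.default_rng(0), length)
        path = make_genbank(tmp_path / "t.gb", "t", seq, features, circular)
        from mtpaleo.genome_io import read_genbank, unify_names

        return unify_names(read_genbank(path, "T1"), {})

    def test_span_of_two_gene_block(self, tmp_path):
        g = self._toy(tmp_path, [
            ("a", "CDS", [(100, 400, 1)], False),
            ("b", "CDS", [(500, 900, 1)], False),
        ])
        t1 = order("T1", "+a +b")
        t2 = order("T2", "+a +b")
        catalog, seqs = identify_blocks([t1, t2], "T1")
        recs = block_coordinates(seqs[0], g, catalog)
        assert recs[0]["start"] == 100 and recs[0]["end"] == 900
        assert recs[0]["strand"] == "+"

    def test_origin_wrapping_block_two_rows(self, tmp_path):
        g = self._toy(tmp_path, [
            ("a", "CDS", [(1800, 1950, 1)], False),
            ("b", "CDS", [(50, 300, 1)], False),
            ("c", "CDS", [(800, 1000, 1)], False),
        ])
        # a..b wrap the origin in T1; T2 breaks the c-a adjacency so [a,b]
        # and [c] stay separate blocks
        t1 = order("T1", "+c +a +b")
        t2 = order("T2", "+c -b -a")
        catalog, seqs = identify_blocks([t1, t2], "T1")
        recs = block_coordinates(seqs[0], g, catalog)
        wrapped = [r for r in recs if r["wrapped"]]
        assert len(wrapped) == 2
        assert {(r["start"], r["end"]) for r in wrapped} == {
            (1800, 2000), (0, 300)
        }
        assert len({r["occurrence"] for r in wrapped}) == 1

    def test_missing_gene_error(self, tmp_path):
        g = self._toy(tmp_path, [("a", "CDS", [(100, 400, 1)], False)])
        t1 = order("T1", "+a +b")
        t2 = order("T2", "+a +b")
        catalog, seqs = identify_blocks([t1, t2], "T1")
        with pytest.raises(SyntenyError, match="missing"):
            block_coordinates(seqs[0], g, catalog)
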