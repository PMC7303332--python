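"""GenBank parsing, nomenclature unification, gene-order extraction."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import given, strategies as st

from mtpaleo.genome_io import (
    GeneOrder,
    GeneToken,
    GenomeIOError,
    canonicalize,
    extract_gene_order,
    read_genbank,
    read_gene_order_tsv,
    unify_names,
    write_gene_order_tsv,
)

from conftest import make_genbank, random_dna


def T(symbol, sign=1, part=0, copy=1):
    return GeneToken(symbol, exon_part=part, copy_index=copy, sign=sign)


class TestReadGenbank:
    def test_minimal_two_gene_record(self, tmp_path):
        rng = np.random.default_rng(0)
        seq = random_dna(rng, 1000)
        path = make_genbank(
            tmp_path / "toy.gb", "toy", seq,
            [("cox1", "CDS", [(100, 400, 1)], False),
             ("rrn5", "rRNA", [(500, 700, -1)], False)],
        )
        g = read_genbank(path, "toy")
        assert g.seq_length == 1000 and g.circular
        assert [(f.name, f.strand) for f in g.features] == [
            ("cox1", 1), ("rrn5", -1)
        ]

    def test_join_complement_across_origin(self, tmp_path):
        # CDS on the minus strand spanning the origin: join of the tail and
        # head of the sequence.  Coordinates checked against the raw string.
        rng = np.random.default_rng(1)
        seq = random_dna(rng, 600)
        path = make_genbank(
            tmp_path / "wrap.gb", "wrap", seq,
            [("nad9", "CDS", [(550, 600, -1), (0, 40, -1)], False),
             ("rrn5", "rRNA", [(200, 300, 1)], False)],
        )
        g = read_genbank(path, "wrap")
        nad9 = next(f for f in g.features if f.name == "nad9")
        assert nad9.strand == -1
        assert sorted(nad9.segments) == [(0, 40), (550, 600)]
        for s, e in nad9.segments:
            assert seq[s:e] == g.sequence[s:e]

    def test_pseudo_qualifier(self, tmp_path):
        seq = random_dna(np.random.default_rng(2), 400)
        path = make_genbank(
            tmp_path / "p.gb", "p", seq,
            [("atp6", "CDS", [(10, 100, 1)], True),
             ("rrn5", "rRNA", [(150, 250, 1)], False)],
        )
        g = read_genbank(path, "p")
        assert next(f for f in g.features if f.name == "atp6").pseudo

    def test_unreadable_file(self, tmp_path):
        bad = tmp_path / "bad.gb"
        bad.write_text("this is not genbank\n")
        with pytest.raises(GenomeIOError):
            read_genbank(bad, "x")


class TestUnifyNames:
    def test_synonym_applied(self, tmp_path):
        seq = random_dna(np.random.default_rng(3), 300)
        path = make_genbank(
            tmp_path / "s.gb", "s", seq,
            [("COX1", "CDS", [(10, 100, 1)], False)],
        )
        g = unify_names(read_genbank(path, "s"), {"COX1": "cox1"})
        assert g.features[0].name == "cox1"

    def test_trna_styles_unify(self, tmp_path):
        seq = random_dna(np.random.default_rng(4), 500)
        path = make_genbank(
            tmp_path / "t.gb", "t", seq,
            [("trnY-GUA", "tRNA", [(10, 80, 1)], False),
             ("trnY(GUA)", "tRNA", [(200, 270, 1)], False)],
        )
        g = unify_names(read_genbank(path, "t"))
        assert [f.name for f in g.features] == ["trnY(GUA)", "trnY(GUA)"]
        assert [f.copy_index for f in g.features] == [1, 2]

    def test_empty_synonyms_identity(self, tmp_path):
        seq = random_dna(np.random.default_rng(5), 300)
        path = make_genbank(
            tmp_path / "e.gb", "e", seq,
            [("foo", "CDS", [(10, 100, 1)], False)],
        )
        g0 = read_genbank(path, "e")
        g1 = unify_names(g0, {})
        assert [f.name for f in g1.features] == [f.name for f in g0.features]


class TestExtractGeneOrder:
    def test_order_and_signs(self, tmp_path):
        seq = random_dna(np.random.default_rng(6), 1000)
        path = make_genbank(
            tmp_path / "o.gb", "o", seq,
            [("a", "CDS", [(10, 60, 1)], False),
             ("b", "CDS", [(200, 260, -1)], False),
             ("c", "CDS", [(500, 560, 1)], False)],
        )
        order = extract_gene_order(unify_names(read_genbank(path, "o"), {}))
        assert [str(t) for t in order.tokens] == ["+a", "-b", "+c"]

    def test_trans_spliced_split(self, tmp_path):
        # nad1 exon clusters separated by another gene become two tokens
        seq = random_dna(np.random.default_rng(7), 5000)
        feats = [
            ("nad1", "CDS", [(100, 200, 1), (4000, 4100, 1)], False),
            ("cox2", "CDS", [(1000, 1400, 1)], False),
        ]
        path = make_genbank(tmp_path / "ts.gb", "ts", seq, feats)
        g = unify_names(read_genbank(path, "ts"), {})
        split = extract_gene_order(g, split_trans_spliced=True)
        assert [str(t) for t in split.tokens] == ["+nad1_p1", "+cox2",
                                                  "+nad1_p2"]
        joined = extract_gene_order(g, split_trans_spliced=False)
        assert [str(t) for t in joined.tokens] == ["+nad1", "+cox2"]

    def test_cis_spliced_not_split(self, tmp_path):
        # adjacent exons with no other gene between them stay one token
        seq = random_dna(np.random.default_rng(8), 3000)
        feats = [
            ("nad4", "CDS", [(100, 200, 1), (400, 500, 1)], False),
            ("cox3", "CDS", [(1000, 1400, 1)], False),
        ]
        path = make_genbank(tmp_path / "cs.gb", "cs", seq, feats)
        g = unify_names(read_genbank(path, "cs"), {})
        order = extract_gene_order(g, split_trans_spliced=True)
        assert [str(t) for t in order.tokens] == ["+nad4", "+cox3"]

    def test_pseudo_excluded_by_default(self, tmp_path):
        seq = random_dna(np.random.default_rng(9), 500)
        path = make_genbank(
            tmp_path / "pe.gb", "pe", seq,
            [("a", "CDS", [(10, 60, 1)], True),
             ("b", "CDS", [(100, 160, 1)], False)],
        )
        g = unify_names(read_genbank(path, "pe"), {})
        assert [t.symbol for t in extract_gene_order(g).tokens] == ["b"]
        both = extract_gene_order(g, include_pseudo=True)
        assert [t.symbol for t in both.tokens] == ["a", "b"]

    def test_no_genes_error(self, tmp_path):
        seq = random_dna(np.random.default_rng(10), 300)
        path = make_genbank(tmp_path / "ng.gb", "ng", seq,
                            [("a", "CDS", [(10, 60, 1)], True)])
        g = read_genbank(path, "ng")
        with pytest.raises(GenomeIOError, match="no genes"):
            extract_gene_order(g)


class TestCanonicalize:
    def test_rotation(self):
        o = GeneOrder("x", [T("b"), T("rrn5"), T("c")], circular=True)
        assert [str(t) for t in canonicalize(o).tokens] == ["+rrn5", "+c",
                                                            "+b"]

    def test_reflection_when_anchor_negative(self):
        # (-rrn5, +x, -y) reflects to (+rrn5, +y, -x): reversing the list
        # and flipping every sign, then rotating rrn5 to the front
        o = GeneOrder("x", [T("rrn5", -1), T("x"), T("y", -1)], circular=True)
        assert [str(t) for t in canonicalize(o).tokens] == ["+rrn5", "+y",
                                                            "-x"]

    def test_idempotent(self):
        o = GeneOrder("x", [T("a", -1), T("rrn5", -1), T("c")], circular=True)
        once = canonicalize(o)
        assert canonicalize(once) == once

    def test_anchor_missing_and_duplicated(self):
        o = GeneOrder("x", [T("a"), T("b")], circular=True)
        with pytest.raises(GenomeIOError, match="absent"):
            canonicalize(o)
        o2 = GeneOrder("x", [T("rrn5"), T("rrn5", copy=2)], circular=True)
        with pytest.raises(GenomeIOError, match="2 times"):
            canonicalize(o2)

    def test_preserves_token_multiset_and_adjacency(self):
        o = GeneOrder(
            "x", [T("a"), T("rrn5", -1), T("b", -1), T("c")], circular=True
        )
        c = canonicalize(o)
        orig = sorted((t.symbol, t.copy_index) for t in o.tokens)
        canon = sorted((t.symbol, t.copy_index) for t in c.tokens)
        assert orig == canon

        def adjacencies(order):
            toks = [(t.gene, t.sign) for t in order.tokens]
            pairs = set()
            for i in range(len(toks)):
                x, y = toks[i], toks[(i + 1) % len(toks)]
                pairs.add(min((x, y), ((y[0], -y[1]), (x[0], -x[1]))))
            return pairs

        assert adjacencies(o) == adjacencies(c)


SYMBOLS = st.sampled_from(["cox1", "nad1", "rrn5", "trnY(GUA)", "atp9"])


@st.composite
def gene_orders(draw):
    n = draw(st.integers(2, 8))
    symbols = draw(
        st.lists(SYMBOLS, min_size=n, max_size=n)
    )
    counts: dict[str, int] = {}
    toks = []
    for s in symbols:
        counts[s] = counts.get(s, 0) + 1
        toks.append(
            GeneToken(s, copy_index=counts[s],
                      sign=draw(st.sampled_from([1, -1])))
        )
    return GeneOrder("h", toks, circular=draw(st.booleans()))


class TestTsvRoundTrip:
    @given(gene_orders())
    def test_write_read_identity(self, generated_order):
        import tempfile
        from pathlib import Path

        with tempfile.TemporaryDirectory() as td:
            path = Path(td) / "o.tsv"
            write_gene_order_tsv(generated_order, path)
            assert read_gene_order_tsv(path) == generated_order

    def test_signed_token_parsing(self, tmp_path):
        p = tmp_path / "o.tsv"
        p.write_text("# taxon=x\tcircular=1\n0\t-cox1\t\n1\t+nad1_p2\t\n")
        order = read_gene_order_tsv(p)
        assert order.tokens[0] == T("cox1", -1)
        assert order.tokens[1] == T("nad1", 1, part=2)

    def test_empty_file_error(self, tmp_path):
        p = tmp_path / "empty.tsv"
        p.write_text("")
        with pytest.raises(GenomeIOError):
            read_gene_order_tsv(p)

    def test_duplicate_position_error(self, tmp_path):
        p = tmp_path / "dup.tsv"
        p.write_text("# taxon=x\tcircular=1\n0\t+a\t\n0\t+b\t\n")
        with pytest.raises(GenomeIOError, match="duplicate position"):
            read_gene_order_tsv(p)
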