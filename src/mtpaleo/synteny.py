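"""Basic syntenic blocks from signed gene orders.

A *basic syntenic block* is a maximal run of genes whose order and relative
orientation is conserved — possibly as a reversed unit — in every genome
that contains those genes.  Blocks are the atomic units of the
rearrangement analysis: each taxon's genome is re-expressed as a signed
sequence of block identifiers, and reversions, gains, losses and
duplications are then counted on block arrangements rather than on raw
gene orders.

Blocks are built from *conserved adjacencies*: an ordered signed gene pair
(x -> y) that appears, with consistent relative orientation, wherever both
genes occur.  Chains of conserved adjacencies (transitive closure) are the
multi-gene blocks; genes in no chain become single-gene blocks.  Blocks are
numbered by first appearance in a designated reference taxon, which makes
the catalog deterministic regardless of input order.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

from .genome_io import AnnotatedGenome, GeneOrder, GeneToken

logger = logging.getLogger(__name__)

__all__ = [
    "Block",
    "BlockCatalog",
    "BlockSequence",
    "SyntenyError",
    "conserved_adjacencies",
    "identify_blocks",
    "expand",
    "block_coordinates",
]

Gene = tuple[str, int]  # (symbol, exon_part) — copy-number blind identity
SignedGene = tuple[Gene, int]


class SyntenyError(ValueError):
    pass


@dataclass(frozen=True)
class Block:
    block_id: int
    genes: tuple[SignedGene, ...]  # orientation relative to block forward
    label: str = ""

    def __post_init__(self) -> None:
        if not self.genes:
            raise ValueError("block gene list must be nonempty")

    def reversed_genes(self) -> tuple[SignedGene, ...]:
        return tuple((g, -s) for g, s in reversed(self.genes))


@dataclass
class BlockCatalog:
    blocks: list[Block]
    reference_taxon: str

    def __post_init__(self) -> None:
        seen: set[Gene] = set()
        for b in self.blocks:
            for g, _ in b.genes:
                if g in seen:
                    raise SyntenyError(f"gene {g} assigned to two blocks")
                seen.add(g)

    def __getitem__(self, block_id: int) -> Block:
        for b in self.blocks:
            if b.block_id == block_id:
                return b
        raise KeyError(block_id)

    def __len__(self) -> int:
        return len(self.blocks)

    def gene_to_block(self) -> dict[Gene, int]:
        return {g: b.block_id for b in self.blocks for g, _ in b.genes}

    def to_json(self, path: str | Path) -> None:
        payload = [
            {
                "block_id": b.block_id,
                "genes": [[list(g), s] for g, s in b.genes],
                "label": b.label,
            }
            for b in self.blocks
        ]
        Path(path).write_text(
            json.dumps({"reference_taxon": self.reference_taxon, "blocks": payload},
                       indent=1)
        )

    @classmethod
    def from_json(cls, path: str | Path) -> "BlockCatalog":
        data = json.loads(Path(path).read_text())
        blocks = [
            Block(
                block_id=b["block_id"],
                genes=tuple(((g[0][0], g[0][1]), g[1]) for g in b["genes"]),
                label=b.get("label", ""),
            )
            for b in data["blocks"]
        ]
        return cls(blocks=blocks, reference_taxon=data["reference_taxon"])


@dataclass
class BlockSequence:
    """One taxon's genome as a signed arrangement of block ids."""

    taxon_id: str
    arrangement: list[int]  # signed block ids; sign = orientation
    circular: bool = True
    duplicated: list[int] = field(default_factory=list)  # ids occurring >1 time

    def __post_init__(self) -> None:
        counts: dict[int, int] = {}
        for b in self.arrangement:
            counts[abs(b)] = counts.get(abs(b), 0) + 1
        self.duplicated = sorted(k for k, v in counts.items() if v > 1)

    def content(self) -> set[int]:
        return {abs(b) for b in self.arrangement}


# --------------------------------------------------------------------------
# conserved adjacencies
# --------------------------------------------------------------------------


def _signed_tokens(order: GeneOrder) -> list[SignedGene]:
    return [(t.gene, t.sign) for t in order.tokens]


def _adjacency_occurrences(order: GeneOrder) -> list[tuple[SignedGene, SignedGene]]:
    toks = _signed_tokens(order)
    pairs = list(zip(toks, toks[1:]))
    if order.circular and len(toks) > 1:
        pairs.append((toks[-1], toks[0]))
    return pairs


def _canon_pair(
    x: SignedGene, y: SignedGene
) -> tuple[SignedGene, SignedGene]:
    """(x -> y) and its reflection (-y -> -x) are the same adjacency."""
    alt = ((y[0], -y[1]), (x[0], -x[1]))
    return min((x, y), alt)


def conserved_adjacencies(orders: Sequence[GeneOrder]) -> set[tuple[SignedGene, SignedGene]]:
    """All signed adjacencies conserved in every taxon containing both genes.

    An adjacency is conserved only if (a) its two genes occur in exactly the
    same set of taxa — a gene missing from some taxon is evidence of a gain
    or loss, which must surface as a single-gene block rather than hide
    inside a larger one — and (b) in every order, *every* occurrence of
    either gene respects the adjacency (the pair may also appear reflected).
    Genes present in fewer than two taxa never form conserved adjacencies.
    With duplicated genes this keeps interior adjacencies of a
    tandem-duplicated run (consistent in every copy) while splitting its
    boundaries.
    """
    if len(orders) < 2:
        raise SyntenyError("need at least two gene orders")
    presence: dict[Gene, frozenset] = {}
    occupancy: dict[Gene, set] = {}
    for o in orders:
        for g in {t.gene for t in o.tokens}:
            occupancy.setdefault(g, set()).add(o.taxon_id)
    presence = {g: frozenset(s) for g, s in occupancy.items()}

    candidate: set[tuple[SignedGene, SignedGene]] = set()
    for o in orders:
        for x, y in _adjacency_occurrences(o):
            if (
                len(presence[x[0]]) >= 2
                and presence[x[0]] == presence[y[0]]
            ):
                candidate.add(_canon_pair(x, y))

    conserved: set[tuple[SignedGene, SignedGene]] = set()
    for pair in candidate:
        (gx, sx), (gy, sy) = pair
        if _pair_holds_everywhere(orders, gx, sx, gy, sy):
            conserved.add(pair)
    return conserved


def _pair_holds_everywhere(
    orders: Sequence[GeneOrder], gx: Gene, sx: int, gy: Gene, sy: int
) -> bool:
    """True iff every occurrence of gx/gy in every order containing both
    genes respects the adjacency (gx,sx) -> (gy,sy), up to reflection."""
    for o in orders:
        genes_here = {t.gene for t in o.tokens}
        if gx not in genes_here or gy not in genes_here:
            continue
        toks = _signed_tokens(o)
        n = len(toks)

        def nbr(i: int, step: int):
            j = i + step
            if 0 <= j < n:
                return toks[j]
            return toks[j % n] if o.circular else None

        for i, t in enumerate(toks):
            if t[0] == gx:
                # this x must be followed (in its own orientation) by y
                nxt = nbr(i, 1 if t[1] == sx else -1)
                want = (gy, sy if t[1] == sx else -sy)
                if nxt != want:
                    return False
            if t[0] == gy:
                prv = nbr(i, -1 if t[1] == sy else 1)
                want = (gx, sx if t[1] == sy else -sx)
                if prv != want:
                    return False
    return True


# --------------------------------------------------------------------------
# block identification
# --------------------------------------------------------------------------


def identify_blocks(
    orders: Sequence[GeneOrder], reference: str
) -> tuple[BlockCatalog, list[BlockSequence]]:
    """Chain conserved adjacencies into blocks and project every taxon.

    Blocks are maximal chains of conserved adjacencies; every gene outside a
    chain becomes a single-gene block.  Blocks are numbered by first
    appearance in the reference taxon's arrangement (then by first
    appearance in the remaining taxa, in input order, for blocks absent from
    the reference).
    """
    by_id = {o.taxon_id: o for o in orders}
    if reference not in by_id:
        raise SyntenyError(f"reference taxon {reference!r} not among inputs")

    adjacencies = conserved_adjacencies(orders)

    # Chain genes via their ends.  Each gene g has a left end (g, -1) and a
    # right end (g, +1) in its own forward orientation; adjacency
    # ((gx,sx) -> (gy,sy)) joins end (gx, sx) to end (gy, -sy).
    joined: dict[tuple[Gene, int], tuple[Gene, int]] = {}
    conflicts: set[tuple[Gene, int]] = set()
    for (gx, sx), (gy, sy) in adjacencies:
        e1, e2 = (gx, sx), (gy, -sy)
        for a, b in ((e1, e2), (e2, e1)):
            if a in joined and joined[a] != b:
                conflicts.add(a)
            joined[a] = b
    for e in conflicts:
        mate = joined.pop(e, None)
        if mate is not None and joined.get(mate) == e:
            joined.pop(mate, None)
        logger.info("adjacency conflict at gene end %s; splitting", e)

    all_genes: list[Gene] = []
    seen_genes: set[Gene] = set()
    ordered_taxa = [by_id[reference]] + [o for o in orders if o.taxon_id != reference]
    for o in ordered_taxa:
        for t in o.tokens:
            if t.gene not in seen_genes:
                seen_genes.add(t.gene)
                all_genes.append(t.gene)

    # walk chains
    assigned: set[Gene] = set()
    chains: list[list[SignedGene]] = []
    for g in all_genes:
        if g in assigned:
            continue
        # walk left from g's left end
        chain: list[SignedGene] = [(g, 1)]
        assigned.add(g)
        end = (g, -1)  # extend off the left end
        while end in joined:
            nxt_end = joined[end]
            ng, ns = nxt_end
            if ng in assigned:
                break  # circular chain closes on itself
            chain.insert(0, (ng, ns))
            assigned.add(ng)
            end = (ng, -ns)
        end = (g, 1)
        while end in joined:
            nxt_end = joined[end]
            ng, ns = nxt_end
            if ng in assigned:
                break
            chain.append((ng, -ns))
            assigned.add(ng)
            end = (ng, -ns)
        chains.append(chain)

    # orient & number blocks by the reference taxon (or first containing taxon)
    def first_occurrence(chain: list[SignedGene]) -> tuple[int, int, int]:
        genes = {g for g, _ in chain}
        for ti, o in enumerate(ordered_taxa):
            for pi, t in enumerate(o.tokens):
                if t.gene in genes:
                    return (ti, pi, 0)
        raise RuntimeError("unreachable: chain gene in no taxon")

    chains.sort(key=first_occurrence)
    blocks: list[Block] = []
    for bid, chain in enumerate(chains, start=1):
        # a chain closing on itself is a wholly conserved circular genome;
        # cut it at the reference taxon's first token for a canonical form
        cyclic = (
            len(chain) > 1
            and joined.get((chain[0][0], -chain[0][1]))
            == (chain[-1][0], chain[-1][1])
        )
        ti, pi, _ = first_occurrence(chain)
        tok = ordered_taxa[ti].tokens[pi]
        rel = dict(chain)
        if tok.sign != rel[tok.gene]:
            chain = [(g, -s) for g, s in reversed(chain)]
        if cyclic:
            idx = next(i for i, (g, _) in enumerate(chain) if g == tok.gene)
            chain = chain[idx:] + chain[:idx]
        blocks.append(Block(block_id=bid, genes=tuple(chain)))

    catalog = BlockCatalog(blocks=blocks, reference_taxon=reference)
    seqs = [_project(o, catalog) for o in orders]
    return catalog, seqs


def _project(order: GeneOrder, catalog: BlockCatalog) -> BlockSequence:
    """Express one taxon's gene order as a signed block arrangement.

    A block's genes that are absent from this taxon are treated as gaps:
    the occurrence must match the block's gene list restricted to the
    taxon's gene set (forward or reversed-and-flipped).
    """
    g2b = catalog.gene_to_block()
    blocks_by_id = {b.block_id: b for b in catalog.blocks}
    toks = _signed_tokens(order)
    present = {g for g, _ in toks}

    def variants(bid: int) -> list[tuple[tuple[SignedGene, ...], int]]:
        block = blocks_by_id[bid]
        fwd = tuple(x for x in block.genes if x[0] in present)
        rev = tuple(x for x in block.reversed_genes() if x[0] in present)
        return [(fwd, 1), (rev, -1)]

    arrangement: list[int] = []
    i, n = 0, len(toks)
    consumed = 0
    # rotate a circular order so it does not start mid-block
    if order.circular and n > 1:
        first_bid = g2b.get(toks[0][0])
        if first_bid is not None:
            k = 0
            while k < n and g2b.get(toks[-1 - k][0]) == first_bid:
                k += 1
            if 0 < k < n:
                toks = toks[-k:] + toks[:-k]
            elif k == n:
                # the whole circle is one block: rotate to a matching start
                for variant, _ in variants(first_bid):
                    hit = next(
                        (
                            r
                            for r in range(n)
                            if toks[r] == variant[0]
                            and tuple(toks[(r + t) % n] for t in range(n))
                            == variant
                        ),
                        None,
                    )
                    if hit is not None:
                        toks = toks[hit:] + toks[:hit]
                        break
    while consumed < n:
        g, s = toks[i % n]
        bid = g2b.get(g)
        if bid is None:
            i += 1
            consumed += 1
            continue
        matched = False
        for variant, sign in variants(bid):
            if variant and variant[0][0] == g and variant[0][1] == s:
                L = len(variant)
                window = [toks[(i + k) % n] for k in range(L)]
                if tuple(window) == variant:
                    arrangement.append(sign * bid)
                    i += L
                    consumed += L
                    matched = True
                    break
        if not matched:
            raise RuntimeError(
                f"internal error: block {bid} not contiguous in "
                f"{order.taxon_id} at gene {g} — adjacency conservation bug"
            )
    return BlockSequence(
        taxon_id=order.taxon_id, arrangement=arrangement, circular=order.circular
    )


# --------------------------------------------------------------------------
# expansion & coordinates
# --------------------------------------------------------------------------


def expand(seq: BlockSequence, catalog: BlockCatalog) -> GeneOrder:
    """Concatenate block gene lists (honouring signs) back to a gene order."""
    blocks_by_id = {b.block_id: b for b in catalog.blocks}
    tokens: list[GeneToken] = []
    counts: dict[Gene, int] = {}
    for sb in seq.arrangement:
        bid = abs(sb)
        if bid not in blocks_by_id:
            raise SyntenyError(f"unknown block id {bid}")
        genes = blocks_by_id[bid].genes if sb > 0 else blocks_by_id[bid].reversed_genes()
        for (sym, part), s in genes:
            counts[(sym, part)] = counts.get((sym, part), 0) + 1
            tokens.append(
                GeneToken(sym, exon_part=part, copy_index=counts[(sym, part)], sign=s)
            )
    return GeneOrder(seq.taxon_id, tokens, circular=seq.circular)


def block_coordinates(
    seq: BlockSequence, genome: AnnotatedGenome, catalog: BlockCatalog,
    order: GeneOrder | None = None,
) -> list[dict]:
    """Genomic span of each block occurrence, 0-based half-open, with strand.

    Returns one record per occurrence; an occurrence wrapping the origin is
    reported with two ``(start, end)`` rows sharing one occurrence index.
    """
    from .genome_io import extract_gene_order

    if order is None:
        order = extract_gene_order(genome)
    # locate each gene's span in the genome
    span_by_gene: dict[tuple[Gene, int], tuple[int, int]] = {}
    for f in genome.features:
        span_by_gene[((f.name, 0), f.copy_index)] = (f.start, f.end)
        # exon-part tokens share the parent feature's segments
        for part, (s, e) in enumerate(f.segments, start=1):
            span_by_gene[((f.name, part), f.copy_index)] = (s, e)

    blocks_by_id = {b.block_id: b for b in catalog.blocks}
    records: list[dict] = []
    used: dict[Gene, int] = {}
    for occ_idx, sb in enumerate(seq.arrangement):
        bid = abs(sb)
        block = blocks_by_id[bid]
        spans: list[tuple[int, int]] = []
        for g, _ in block.genes:
            used[g] = used.get(g, 0) + 1
            key = (g, used[g])
            if key not in span_by_gene and (g, 1) in span_by_gene:
                key = (g, 1)
            if key not in span_by_gene:
                raise SyntenyError(
                    f"gene {g} of block {bid} missing from genome "
                    f"{genome.taxon_id}"
                )
            spans.append(span_by_gene[key])
        lo = min(s for s, _ in spans)
        hi = max(e for _, e in spans)
        # detect origin wrap: gene spans split across the ends of the sequence
        span_len = hi - lo
        if genome.circular and span_len > genome.seq_length * 0.75 and len(spans) > 1:
            inner = sorted(spans)
            gaps = [
                (inner[i + 1][0] - inner[i][1], inner[i][1], inner[i + 1][0])
                for i in range(len(inner) - 1)
            ]
            big = max(gaps)
            if big[0] > genome.seq_length - span_len:
                records.append(
                    {
                        "block_id": bid,
                        "occurrence": occ_idx,
                        "start": big[2],
                        "end": genome.seq_length,
                        "strand": "+" if sb > 0 else "-",
                        "wrapped": True,
                    }
                )
                records.append(
                    {
                        "block_id": bid,
                        "occurrence": occ_idx,
                        "start": 0,
                        "end": big[1],
                        "strand": "+" if sb > 0 else "-",
                        "wrapped": True,
                    }
                )
                continue
        records.append(
            {
                "block_id": bid,
                "occurrence": occ_idx,
                "start": lo,
                "end": hi,
                "strand": "+" if sb > 0 else "-",
                "wrapped": False,
            }
        )
    return records


def write_bed(records: Iterable[dict], taxon_id: str, path: str | Path) -> None:
    with Path(path).open("w") as fh:
        for r in records:
            fh.write(
                f"{taxon_id}\t{r['start']}\t{r['end']}\tblock_{r['block_id']}"
                f".occ{r['occurrence']}\t0\t{r['strand']}\n"
            )


def project_order(order: GeneOrder, catalog: BlockCatalog) -> BlockSequence:
    """Express a gene order as a signed block arrangement over an existing
    catalog (genes outside the catalog are ignored)."""
    return _project(order, catalog)
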