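"""Annotated organellar genomes and signed gene orders.

Plant mitochondrial genomes are typically circular molecules of a few
hundred kb carrying 30-60 genes.  Comparative structural analysis works on
the *order and orientation* of those genes rather than on nucleotide
alignment, so the first step of the pipeline is to reduce an annotated
GenBank record to a circular sequence of signed gene tokens, with gene
nomenclature unified across annotation styles and the sequence rotated to a
fixed anchor gene (``rrn5`` by default) so that arrangements from different
taxa are directly comparable.

Coordinates are 0-based half-open internally; GenBank's 1-based inclusive
intervals are converted at the parsing boundary.  Exon clusters of
trans-spliced genes (e.g. ``nad1``) that are separated by other genes are
treated as independent order tokens, since they rearrange independently.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from Bio import SeqIO

logger = logging.getLogger(__name__)

DEFAULT_ANCHOR = "rrn5"

__all__ = [
    "GeneToken",
    "GeneFeature",
    "AnnotatedGenome",
    "GeneOrder",
    "GenomeIOError",
    "read_genbank",
    "unify_names",
    "default_synonyms",
    "extract_gene_order",
    "canonicalize",
    "read_gene_order_tsv",
    "write_gene_order_tsv",
]


class GenomeIOError(ValueError):
    """Raised for malformed inputs (GenBank, TSV) or contract violations."""


# --------------------------------------------------------------------------
# domain types
# --------------------------------------------------------------------------


@dataclass(frozen=True, order=True)
class GeneToken:
    """One signed element of a gene order.

    ``exon_part`` is 0 for ordinary genes and 1, 2, ... for the exon
    clusters of a trans-spliced gene.  ``copy_index`` distinguishes multiple
    copies of the same symbol within one genome (assigned in coordinate
    order).  ``sign`` is +1 or -1 (coding strand).
    """

    symbol: str
    exon_part: int = 0
    copy_index: int = 1
    sign: int = 1

    def __post_init__(self) -> None:
        if self.sign not in (1, -1):
            raise ValueError(f"sign must be +1/-1, got {self.sign}")

    @property
    def gene(self) -> tuple[str, int]:
        """Identity used to match tokens across taxa (copy-number blind)."""
        return (self.symbol, self.exon_part)

    def flipped(self) -> "GeneToken":
        return replace(self, sign=-self.sign)

    def __str__(self) -> str:
        s = "+" if self.sign > 0 else "-"
        name = self.symbol
        if self.exon_part:
            name += f"_p{self.exon_part}"
        if self.copy_index != 1:
            name += f"#{self.copy_index}"
        return s + name

    @classmethod
    def parse(cls, text: str) -> "GeneToken":
        m = re.fullmatch(r"([+-]?)([^#\s]+?)(?:_p(\d+))?(?:#(\d+))?", text.strip())
        if not m:
            raise GenomeIOError(f"unparseable gene token {text!r}")
        sign = -1 if m.group(1) == "-" else 1
        return cls(
            symbol=m.group(2),
            exon_part=int(m.group(3) or 0),
            copy_index=int(m.group(4) or 1),
            sign=sign,
        )


@dataclass
class GeneFeature:
    """A gene-bearing annotation: one or more genomic segments on a strand."""

    name: str
    kind: str  # "protein" | "tRNA" | "rRNA"
    strand: int
    segments: list[tuple[int, int]]  # 0-based half-open, sorted by start
    pseudo: bool = False
    copy_index: int = 1

    def __post_init__(self) -> None:
        if not self.segments:
            raise ValueError(f"feature {self.name}: no segments")
        if self.strand not in (1, -1):
            raise ValueError(f"feature {self.name}: bad strand {self.strand}")

    @property
    def start(self) -> int:
        return min(s for s, _ in self.segments)

    @property
    def end(self) -> int:
        return max(e for _, e in self.segments)


@dataclass
class AnnotatedGenome:
    taxon_id: str
    seq_length: int
    circular: bool
    features: list[GeneFeature] = field(default_factory=list)
    sequence: str | None = None

    def __post_init__(self) -> None:
        if not self.taxon_id:
            raise ValueError("taxon_id must be nonempty")
        if self.seq_length <= 0:
            raise ValueError("seq_length must be positive")
        for f in self.features:
            for s, e in f.segments:
                if not (0 <= s < e <= self.seq_length):
                    raise GenomeIOError(
                        f"feature {f.name}: segment ({s},{e}) outside "
                        f"[0,{self.seq_length})"
                    )


@dataclass
class GeneOrder:
    """A (usually circular) arrangement of signed gene tokens for one taxon."""

    taxon_id: str
    tokens: list[GeneToken]
    circular: bool = True

    def __len__(self) -> int:
        return len(self.tokens)

    def __iter__(self):
        return iter(self.tokens)

    def __eq__(self, other) -> bool:
        if not isinstance(other, GeneOrder):
            return NotImplemented
        return (
            self.taxon_id == other.taxon_id
            and self.tokens == other.tokens
            and self.circular == other.circular
        )

    def reflected(self) -> "GeneOrder":
        """The same molecule read from the other strand."""
        return GeneOrder(
            self.taxon_id,
            [t.flipped() for t in reversed(self.tokens)],
            self.circular,
        )


# --------------------------------------------------------------------------
# GenBank parsing
# --------------------------------------------------------------------------

_KIND_BY_TYPE = {"CDS": "protein", "tRNA": "tRNA", "rRNA": "rRNA"}


def _feature_name(feat) -> str | None:
    for key in ("gene", "product", "locus_tag"):
        if key in feat.qualifiers:
            return str(feat.qualifiers[key][0])
    return None


def read_genbank(path: str | Path, taxon_id: str) -> AnnotatedGenome:
    """Parse a GenBank flat file into an :class:`AnnotatedGenome`.

    Gene-bearing features (CDS / tRNA / rRNA, with plain ``gene`` features
    used as fallback for names only) become :class:`GeneFeature` records;
    ``join(...)`` locations become multi-segment features; circular topology
    is read from the LOCUS line; the ``/pseudo`` qualifier is honoured.
    """
    path = Path(path)
    try:
        record = SeqIO.read(str(path), "genbank")
    except Exception as exc:  # Biopython raises assorted ValueErrors
        raise GenomeIOError(f"cannot parse GenBank file {path}: {exc}") from exc
    try:
        seq_len = len(record.seq)
    except Exception as exc:
        raise GenomeIOError(f"record in {path} has no sequence") from exc
    if seq_len == 0:
        raise GenomeIOError(f"record in {path} has an empty sequence")
    circular = record.annotations.get("topology", "linear") == "circular"

    features: list[GeneFeature] = []
    seen_spans: set[tuple[str, tuple[tuple[int, int], ...]]] = set()
    for feat in record.features:
        if feat.type not in _KIND_BY_TYPE:
            continue
        name = _feature_name(feat)
        if name is None:
            logger.info("%s: skipping unnamed %s feature", taxon_id, feat.type)
            continue
        segments: list[tuple[int, int]] = []
        for part in feat.location.parts:
            s, e = int(part.start), int(part.end)
            if not (0 <= s < e <= seq_len):
                raise GenomeIOError(
                    f"feature {name} in {path.name}: location ({s},{e}) "
                    f"outside sequence [0,{seq_len})"
                )
            segments.append((s, e))
        segments.sort()
        strand = feat.location.strand
        if strand is None:
            strand = 1
        key = (name, tuple(segments))
        if key in seen_spans:  # gene + CDS pairs annotate the same span
            continue
        seen_spans.add(key)
        features.append(
            GeneFeature(
                name=name,
                kind=_KIND_BY_TYPE[feat.type],
                strand=int(strand),
                segments=segments,
                pseudo="pseudo" in feat.qualifiers
                or "pseudogene" in feat.qualifiers,
            )
        )
    features.sort(key=lambda f: (f.start, f.end, f.name))
    genome = AnnotatedGenome(
        taxon_id=taxon_id,
        seq_length=seq_len,
        circular=circular,
        features=features,
        sequence=str(record.seq),
    )
    logger.info(
        "%s: parsed %d gene features (%d bp, %s)",
        taxon_id,
        len(features),
        seq_len,
        "circular" if circular else "linear",
    )
    return genome


# --------------------------------------------------------------------------
# nomenclature unification
# --------------------------------------------------------------------------

_TRNA_RE = re.compile(r"^trn([A-Za-z])[\s(\-_]*([A-Za-z]{3})?\)?$", re.IGNORECASE)
_FAMILY_RE = re.compile(
    r"^(nad|cox|atp|rps|rpl|rrn|ccm|sdh|cob|mat|mtt|orf)", re.IGNORECASE
)


def default_synonyms() -> dict[str, str]:
    """A small built-in table for common annotation-style variants."""
    return {
        "coxI": "cox1",
        "coxII": "cox2",
        "coxIII": "cox3",
        "cytb": "cob",
        "apocytochrome b": "cob",
        "matR": "matR",
        "mttB": "mttB",
        "5S ribosomal RNA": "rrn5",
        "18S ribosomal RNA": "rrn18",
        "26S ribosomal RNA": "rrn26",
    }


def _normalize_name(raw: str, synonyms: Mapping[str, str]) -> str:
    if raw in synonyms:
        return synonyms[raw]
    m = _TRNA_RE.match(raw)
    if m:
        aa, anticodon = m.group(1).upper(), m.group(2)
        if anticodon:
            return f"trn{aa}({anticodon.upper()})"
        return f"trn{aa}"
    if _FAMILY_RE.match(raw):
        base = raw.replace(" ", "")
        low = base.lower()
        # conventional mixed-case symbols
        mixed = {
            "matr": "matR", "mttb": "mttB", "ccmb": "ccmB", "ccmc": "ccmC",
            "ccmfc": "ccmFc", "ccmfn": "ccmFn",
        }
        if low in mixed:
            return mixed[low]
        if low.startswith("matr"):
            return "matR"
        return low
    return raw


def unify_names(
    genome: AnnotatedGenome, synonyms: Mapping[str, str] | None = None
) -> AnnotatedGenome:
    """Normalize feature names and assign copy indices.

    Names found in ``synonyms`` are replaced; tRNA and gene-family names are
    case/punctuation folded (``trnY-GUA`` and ``trnY(GUA)`` become one
    symbol).  Unmapped names pass through unchanged and are logged.
    ``copy_index`` is assigned in ascending coordinate order among features
    sharing a normalized symbol.
    """
    if synonyms is None:
        synonyms = default_synonyms()
    new_feats: list[GeneFeature] = []
    for f in sorted(genome.features, key=lambda f: (f.start, f.end, f.name)):
        name = _normalize_name(f.name, synonyms)
        if name == f.name and f.name not in synonyms and not _TRNA_RE.match(f.name):
            if not _FAMILY_RE.match(f.name):
                logger.info(
                    "%s: name %r not in synonym table, kept as-is",
                    genome.taxon_id,
                    f.name,
                )
        new_feats.append(replace(f, name=name, copy_index=1))
    counts: dict[str, int] = {}
    for f in new_feats:
        counts[f.name] = counts.get(f.name, 0) + 1
        f.copy_index = counts[f.name]
    seen = set()
    for f in new_feats:
        key = (f.name, f.copy_index)
        if key in seen:
            raise RuntimeError(f"internal error: duplicate (name, copy) {key}")
        seen.add(key)
    return AnnotatedGenome(
        taxon_id=genome.taxon_id,
        seq_length=genome.seq_length,
        circular=genome.circular,
        features=new_feats,
        sequence=genome.sequence,
    )


# --------------------------------------------------------------------------
# gene-order extraction
# --------------------------------------------------------------------------


def _segment_clusters(
    feature: GeneFeature, other_starts: list[int]
) -> list[list[tuple[int, int]]]:
    """Group a feature's segments; a gap containing another gene's start
    splits the segments into separate (trans-spliced) exon clusters."""
    clusters: list[list[tuple[int, int]]] = [[feature.segments[0]]]
    for prev, cur in zip(feature.segments, feature.segments[1:]):
        gap_lo, gap_hi = prev[1], cur[0]
        if any(gap_lo <= s < gap_hi for s in other_starts):
            clusters.append([cur])
        else:
            clusters[-1].append(cur)
    return clusters


def extract_gene_order(
    genome: AnnotatedGenome,
    include_pseudo: bool = False,
    split_trans_spliced: bool = True,
    drop: Iterable[str] = (),
) -> GeneOrder:
    """Project an annotated genome onto a signed gene order.

    Tokens are ordered by the start coordinate of each exon cluster; the
    token sign is the coding strand.  Pseudogenes are excluded unless
    ``include_pseudo`` (structural analysis treats them as gaps).  Symbols
    in ``drop`` (and unnamed ``orfNNN`` features by default) are excluded.
    """
    drop = set(drop)
    feats = [f for f in genome.features if include_pseudo or not f.pseudo]
    feats = [
        f
        for f in feats
        if f.name not in drop and not re.fullmatch(r"orf\d+[a-z]?", f.name)
    ]
    if not feats:
        raise GenomeIOError(f"{genome.taxon_id}: no genes to extract")
    starts_by_feat: dict[int, list[int]] = {}
    all_starts = [(s, id(f)) for f in feats for s, _ in f.segments]
    for f in feats:
        starts_by_feat[id(f)] = [s for s, fid in all_starts if fid != id(f)]

    entries: list[tuple[int, int, str, GeneToken]] = []
    for f in feats:
        clusters = _segment_clusters(f, starts_by_feat[id(f)])
        if len(clusters) > 1 and split_trans_spliced:
            for i, cl in enumerate(clusters, start=1):
                tok = GeneToken(f.name, exon_part=i, copy_index=f.copy_index,
                                sign=f.strand)
                entries.append((cl[0][0], cl[-1][1], f.name, tok))
        else:
            tok = GeneToken(f.name, exon_part=0, copy_index=f.copy_index,
                            sign=f.strand)
            entries.append((clusters[0][0][0], clusters[0][-1][1], f.name, tok))
    entries.sort(key=lambda e: (e[0], e[1], e[2]))
    return GeneOrder(
        taxon_id=genome.taxon_id,
        tokens=[e[3] for e in entries],
        circular=genome.circular,
    )


# --------------------------------------------------------------------------
# canonical rotation
# --------------------------------------------------------------------------


def canonicalize(order: GeneOrder, anchor: str = DEFAULT_ANCHOR) -> GeneOrder:
    """Rotate a circular order so the anchor gene comes first with sign +1.

    If the anchor lies on the minus strand the whole order is reflected
    (reversed with all signs flipped) before rotation, so that two
    arrangements of the same molecule read from opposite strands
    canonicalize identically.  Idempotent.
    """
    if not order.circular:
        raise GenomeIOError(f"{order.taxon_id}: cannot canonicalize a linear order")
    hits = [i for i, t in enumerate(order.tokens) if t.symbol == anchor]
    if not hits:
        present = sorted({t.symbol for t in order.tokens})
        raise GenomeIOError(
            f"{order.taxon_id}: anchor {anchor!r} absent; choose another anchor "
            f"(e.g. one of {present[:5]})"
        )
    if len(hits) > 1:
        raise GenomeIOError(
            f"{order.taxon_id}: anchor {anchor!r} occurs {len(hits)} times "
            f"(positions {hits}); choose a single-copy anchor"
        )
    work = order
    i = hits[0]
    if work.tokens[i].sign < 0:
        work = work.reflected()
        i = next(j for j, t in enumerate(work.tokens) if t.symbol == anchor)
    toks = work.tokens[i:] + work.tokens[:i]
    return GeneOrder(order.taxon_id, toks, circular=True)


# --------------------------------------------------------------------------
# gene-order TSV exchange format
# --------------------------------------------------------------------------


def write_gene_order_tsv(order: GeneOrder, path: str | Path) -> None:
    """Write the 3-column exchange format: position, signed token, notes."""
    path = Path(path)
    with path.open("w") as fh:
        fh.write(f"# taxon={order.taxon_id}\tcircular={int(order.circular)}\n")
        fh.write("position\ttoken\tnotes\n")
        for i, tok in enumerate(order.tokens):
            fh.write(f"{i}\t{tok}\t\n")


def read_gene_order_tsv(path: str | Path) -> GeneOrder:
    path = Path(path)
    lines = path.read_text().splitlines()
    if not lines:
        raise GenomeIOError(f"{path}: empty gene-order file")
    m = re.match(r"#\s*taxon=(\S+)\tcircular=([01])", lines[0])
    if not m:
        raise GenomeIOError(f"{path}:1: missing '# taxon=...' header")
    taxon_id, circular = m.group(1), bool(int(m.group(2)))
    tokens: list[GeneToken] = []
    positions: set[int] = set()
    for lineno, line in enumerate(lines[1:], start=2):
        if not line.strip() or line.startswith(("#", "position\t")):
            continue
        parts = line.split("\t")
        if len(parts) < 2:
            raise GenomeIOError(f"{path}:{lineno}: expected >=2 tab-separated columns")
        try:
            pos = int(parts[0])
        except ValueError as exc:
            raise GenomeIOError(f"{path}:{lineno}: bad position {parts[0]!r}") from exc
        if pos in positions:
            raise GenomeIOError(f"{path}:{lineno}: duplicate position {pos}")
        positions.add(pos)
        try:
            tokens.append((pos, GeneToken.parse(parts[1])))
        except GenomeIOError as exc:
            raise GenomeIOError(f"{path}:{lineno}: {exc}") from exc
    if not tokens:
        raise GenomeIOError(f"{path}: no gene tokens")
    tokens.sort(key=lambda pt: pt[0])
    return GeneOrder(taxon_id, [t for _, t in tokens], circular)
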