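"""Ground-truth simulator for block-order evolution on a tree.

Histories start from a root genome of ``n_blocks`` syntenic blocks (block 1
carries the ``rrn5`` anchor) and evolve along a rooted tree by reversions,
gene gains (new singleton blocks), gene losses and tandem block
duplications.  The default event mix follows the relative frequencies
observed in Brassica mt evolution (reversions dominating, with occasional
gains, losses and a rare duplication).

In *non-overlap* mode (the default) event spans on any root-to-leaf path
are disjoint and every internal node keeps an event-free path down to at
least one leaf.  Under those conditions the true history is uniquely
recoverable by parsimony, which is what makes simulated histories usable as
exact ground truth for the reconstruction pipeline.  Free mode lifts the
constraints for stress testing.

Optionally each leaf receives a nucleotide sequence: genes get fixed random
sequences shared across taxa, intergenic junctions get per-leaf random
spacers, and each reversion on the leaf's history plants an inverted repeat
pair (one fresh repeat sequence per event, shared by all leaves carrying
the event) at the two block junctions that the reversion created —
emulating repeat-mediated recombination leaving its footprint at block
boundaries.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from .ancestor import Phylogeny, read_newick
from .genome_io import GeneOrder, GeneToken
from .synteny import Block, BlockCatalog, BlockSequence

logger = logging.getLogger(__name__)

__all__ = ["SimulationConfig", "SimulatedHistory", "simulate_history",
           "emit_genbank", "DEFAULT_TREE"]

DEFAULT_TREE = "((((T1,T2),(T3,T4)),(T5,T6)),OG);"

# plant-mt-like gene vocabulary; rrn5 first so it lands in block 1
MT_GENE_VOCABULARY = [
    "rrn5", "rrn18", "rrn26", "atp1", "atp4", "atp6", "atp8", "atp9",
    "cox1", "cox2", "cox3", "cob", "ccmB", "ccmC", "ccmFc", "ccmFn",
    "nad1", "nad2", "nad3", "nad4", "nad5", "nad6", "nad7", "nad9",
    "matR", "mttB", "rps1", "rps3", "rps4", "rps7", "rps12",
    "rpl2", "rpl5", "rpl16",
    "trnC(GCA)", "trnD(GUC)", "trnE(UUC)", "trnF(GAA)", "trnG(GCC)",
    "trnH(GUG)", "trnI(CAU)", "trnK(UUU)", "trnM(CAU)", "trnN(GUU)",
    "trnP(UGG)", "trnQ(UUG)", "trnS(UGA)", "trnW(CCA)", "trnY(GUA)",
]

EVENT_KINDS = ("reversion", "gene_gain", "gene_loss", "block_duplication")
# relative frequencies of structural event kinds in the default mix
DEFAULT_KIND_WEIGHTS = (17, 4, 4, 1)


@dataclass
class SimulationConfig:
    n_blocks: int = 15
    genes_per_block: tuple[int, int] = (1, 5)  # uniform inclusive range
    tree: str = DEFAULT_TREE
    outgroup: str = "OG"
    mean_events_per_branch: float = 1.0
    kind_weights: tuple[int, int, int, int] = DEFAULT_KIND_WEIGHTS
    non_overlap: bool = True
    max_span: int = 3  # longest reversion/duplication span, in blocks
    emit_sequences: bool = False
    repeat_length: int = 200  # bp of planted inverted repeats
    gene_length: tuple[int, int] = (200, 900)
    # plant mt genomes are mostly intergenic: ~40 genes in a 200-360 kb
    # molecule; 2 kb spacers keep that character at test-friendly scale
    spacer_length: int = 2000
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_blocks < 2:
            raise ValueError("need at least 2 blocks")
        if self.mean_events_per_branch < 0:
            raise ValueError("negative event rate")


@dataclass
class TrueEvent:
    kind: str
    span_ids: tuple[int, ...]  # block ids involved (signed for reversions)


@dataclass
class SimulatedHistory:
    config: SimulationConfig
    phylogeny: Phylogeny
    catalog: BlockCatalog
    root_state: BlockSequence
    states: dict[str, BlockSequence]  # leaf label / clade key -> state
    clade_states: dict[frozenset, BlockSequence]
    branch_events: dict[frozenset, list[TrueEvent]]  # keyed by child clade
    leaf_orders: dict[str, GeneOrder]
    sequences: dict[str, str] = field(default_factory=dict)
    planted_repeats: dict[str, list[tuple[int, int, int, str]]] = field(
        default_factory=dict
    )
    block_junctions: dict[str, list[int]] = field(default_factory=dict)
    feature_layout: dict[str, list[tuple[str, str, int, int, int]]] = field(
        default_factory=dict
    )

    def branch_counts(self) -> dict[frozenset, dict[str, int]]:
        out = {}
        for clade, events in self.branch_events.items():
            counts = {k: 0 for k in EVENT_KINDS}
            for e in events:
                counts[e.kind] += 1
            out[clade] = counts
        return out

    def total_events(self) -> int:
        return sum(len(v) for v in self.branch_events.values())


# --------------------------------------------------------------------------
# history generation
# --------------------------------------------------------------------------


def _make_catalog(cfg: SimulationConfig, rng: np.random.Generator) -> BlockCatalog:
    lo, hi = cfg.genes_per_block
    sizes = rng.integers(lo, hi + 1, size=cfg.n_blocks)
    vocab = list(MT_GENE_VOCABULARY)
    blocks: list[Block] = []
    gi = 0
    for bid in range(1, cfg.n_blocks + 1):
        genes = []
        for _ in range(int(sizes[bid - 1])):
            name = vocab[gi] if gi < len(vocab) else f"gene{gi + 1}"
            gi += 1
            sign = 1 if rng.random() < 0.7 else -1
            if name == "rrn5":  # the anchor gene leads block 1 on + strand
                sign = 1
            genes.append(((name, 0), sign))
        blocks.append(Block(block_id=bid, genes=tuple(genes)))
    return BlockCatalog(blocks=blocks, reference_taxon="root")


def _sample_events(
    cfg: SimulationConfig, rng: np.random.Generator, n: int
) -> list[str]:
    k = int(rng.poisson(cfg.mean_events_per_branch)) if n else 0
    w = np.asarray(cfg.kind_weights, dtype=float)
    w = w / w.sum()
    return [EVENT_KINDS[i] for i in rng.choice(4, size=k, p=w)]


def _apply_events(
    state: list[int],
    kinds: list[str],
    used_ids: set[int],
    cfg: SimulationConfig,
    rng: np.random.Generator,
    next_id: list[int],
    catalog_blocks: list[Block],
    gene_counter: list[int],
) -> tuple[list[int], list[TrueEvent], set[int]]:
    """Apply sampled events to a state (anchor block pinned at index 0).

    In non-overlap mode an event's blocks (plus one flanking block for
    reversions) must be untouched on this lineage; unplaceable events are
    dropped with a log message.
    """
    events: list[TrueEvent] = []
    used = used_ids  # shared across the whole tree: spans are never reused,
    # so no convergent (homoplastic) events can arise in non-overlap mode
    for kind in kinds:
        placed = False
        for _ in range(40):  # rejection sampling of a legal placement
            n = len(state)
            if kind == "reversion":
                if n < 3:
                    break
                i = int(rng.integers(1, n - 1))
                L = int(rng.integers(1, min(cfg.max_span, n - i) + 1))
                span = state[i : i + L]
                flanks = {abs(state[i - 1]), abs(state[(i + L) % n])}
                touch = {abs(x) for x in span} | flanks
                if cfg.non_overlap and (touch & used):
                    continue
                state = (
                    state[:i] + [-x for x in reversed(span)] + state[i + L :]
                )
                events.append(TrueEvent("reversion", tuple(span)))
                used |= touch
                placed = True
                break
            if kind == "gene_gain":
                i = int(rng.integers(1, len(state) + 1))
                nbrs = {abs(state[i - 1]), abs(state[i % len(state)])}
                if cfg.non_overlap and (nbrs & used):
                    continue
                bid = next_id[0]
                gname = f"gained{gene_counter[0]}"
                gene_counter[0] += 1
                next_id[0] += 1
                catalog_blocks.append(
                    Block(block_id=bid, genes=(((gname, 0), 1),))
                )
                state = state[:i] + [bid] + state[i:]
                events.append(TrueEvent("gene_gain", (bid,)))
                used |= {bid} | nbrs
                placed = True
                break
            if kind == "gene_loss":
                if len(state) < 3:
                    break
                i = int(rng.integers(1, len(state)))
                v = abs(state[i])
                touch = {v, abs(state[i - 1]), abs(state[(i + 1) % len(state)])}
                if cfg.non_overlap and (touch & used):
                    continue
                state = state[:i] + state[i + 1 :]
                events.append(TrueEvent("gene_loss", (v,)))
                used |= touch
                placed = True
                break
            if kind == "block_duplication":
                if len(state) < 3:
                    break
                i = int(rng.integers(1, len(state)))
                L = int(rng.integers(1, min(cfg.max_span, len(state) - i) + 1))
                run = state[i : i + L]
                ids = {abs(x) for x in run}
                ids |= {abs(state[i - 1]), abs(state[(i + L) % len(state)])}
                if cfg.non_overlap and (ids & used):
                    continue
                # tandem duplication
                state = state[: i + L] + run + state[i + L :]
                events.append(TrueEvent("block_duplication", tuple(run)))
                used |= ids
                placed = True
                break
        if not placed and kind in EVENT_KINDS:
            logger.info("dropping unplaceable %s event", kind)
    return state, events, used


def simulate_history(cfg: SimulationConfig) -> SimulatedHistory:
    """Generate a full ground-truth history from a seeded configuration."""
    rng = np.random.default_rng(cfg.seed)
    catalog = _make_catalog(cfg, rng)
    catalog_blocks = list(catalog.blocks)
    phylogeny = _phylogeny_from_config(cfg)

    root_arr = list(range(1, cfg.n_blocks + 1))
    next_id = [cfg.n_blocks + 1]
    gene_counter = [1]

    clade_states: dict[frozenset, BlockSequence] = {}
    branch_events: dict[frozenset, list[TrueEvent]] = {}
    leaf_states: dict[str, BlockSequence] = {}

    ingroup_root = phylogeny.ingroup_root()

    def clade_of(node) -> frozenset:
        return frozenset(l.taxon.label for l in node.leaf_iter())

    def descend(node, state: list[int], used: set[int]) -> None:
        children = node.child_nodes()
        if not children:
            lab = node.taxon.label
            leaf_states[lab] = BlockSequence(lab, list(state), circular=True)
            return
        clade_states[clade_of(node)] = BlockSequence(
            "|".join(sorted(clade_of(node))), list(state), circular=True
        )
        # one child keeps an event-free line so the history is recoverable
        clean = int(rng.integers(0, len(children))) if cfg.non_overlap else -1
        for ci, child in enumerate(children):
            ckey = clade_of(child)
            if cfg.non_overlap and ci == clean:
                branch_events[ckey] = []
                descend(child, list(state), used)
                continue
            kinds = _sample_events(cfg, rng, len(state))
            cstate, events, cused = _apply_events(
                list(state), kinds, used, cfg, rng, next_id,
                catalog_blocks, gene_counter,
            )
            branch_events[ckey] = events
            descend(child, cstate, cused)

    root_state = BlockSequence("root", list(root_arr), circular=True)
    # the outgroup branch is kept event-free: no state is inferred above the
    # ingroup root, so outgroup events would be unidentifiable anyway
    og_leaf = phylogeny.outgroup
    leaf_states[og_leaf] = BlockSequence(og_leaf, list(root_arr), circular=True)
    branch_events[frozenset({og_leaf})] = []
    descend(ingroup_root, list(root_arr), set())

    catalog = BlockCatalog(blocks=catalog_blocks, reference_taxon="root")
    from .synteny import expand

    leaf_orders = {
        lab: expand(seq, catalog) for lab, seq in leaf_states.items()
    }
    history = SimulatedHistory(
        config=cfg,
        phylogeny=phylogeny,
        catalog=catalog,
        root_state=root_state,
        states={**leaf_states},
        clade_states=clade_states,
        branch_events=branch_events,
        leaf_orders=leaf_orders,
    )
    if cfg.emit_sequences:
        _attach_sequences(history, rng)
    return history


def _phylogeny_from_config(cfg: SimulationConfig) -> Phylogeny:
    import io
    import dendropy

    tree = dendropy.Tree.get(
        data=cfg.tree, schema="newick", rooting="force-rooted"
    )
    return Phylogeny(tree=tree, outgroup=cfg.outgroup)


# --------------------------------------------------------------------------
# sequences and GenBank emission
# --------------------------------------------------------------------------

_BASES = np.array(list("ACGT"))


def _random_seq(rng: np.random.Generator, length: int) -> str:
    return "".join(_BASES[rng.integers(0, 4, size=length)])


def _revcomp(s: str) -> str:
    return s.translate(str.maketrans("ACGTN", "TGCAN"))[::-1]


def _attach_sequences(history: SimulatedHistory, rng: np.random.Generator) -> None:
    cfg = history.config
    lo, hi = cfg.gene_length
    gene_seq: dict[tuple[str, int], str] = {}
    for b in history.catalog.blocks:
        for g, _ in b.genes:
            if g not in gene_seq:
                gene_seq[g] = _random_seq(rng, int(rng.integers(lo, hi + 1)))

    # one repeat sequence per reversion event, shared across carrying leaves
    event_repeat: dict[int, str] = {}
    rev_counter = 0
    event_index: dict[frozenset, list[int]] = {}
    for clade, events in sorted(
        history.branch_events.items(), key=lambda kv: sorted(kv[0])
    ):
        idxs = []
        for e in events:
            if e.kind == "reversion":
                event_repeat[rev_counter] = _random_seq(rng, cfg.repeat_length)
                idxs.append(rev_counter)
                rev_counter += 1
            else:
                idxs.append(-1)
        event_index[clade] = idxs

    for leaf, order in history.leaf_orders.items():
        # reversions on the path to this leaf, with their repeat ids
        path_revs: list[tuple[int, tuple[int, ...]]] = []
        for clade, events in history.branch_events.items():
            if leaf not in clade:
                continue
            for e, ridx in zip(events, event_index[clade]):
                if e.kind == "reversion":
                    path_revs.append((ridx, e.span_ids))
        seq_parts: list[str] = []
        junctions: list[int] = []
        arrangement = history.states[leaf].arrangement
        blocks_by_id = {b.block_id: b for b in history.catalog.blocks}
        # map: junction slot j sits before arrangement[j]
        junction_repeats: dict[int, list[str]] = {}
        for ridx, span in path_revs:
            ids = [abs(x) for x in span]
            posns = [
                i for i, x in enumerate(arrangement) if abs(x) in set(ids)
            ]
            if len(posns) != len(ids) or not posns:
                continue  # span disrupted later (free mode); skip planting
            lo_j, hi_j = min(posns), max(posns) + 1
            rep = event_repeat[ridx]
            junction_repeats.setdefault(lo_j, []).append(rep)
            junction_repeats.setdefault(hi_j % len(arrangement), []).append(
                _revcomp(rep)
            )
        pos = 0
        repeats_here: list[tuple[int, int, int, str]] = []
        planted_at: dict[str, list[tuple[int, bool]]] = {}
        layout: list[tuple[str, str, int, int, int]] = []
        for j, sb in enumerate(arrangement):
            spacer = _random_seq(rng, cfg.spacer_length)
            seq_parts.append(spacer)
            pos += len(spacer)
            for rep in junction_repeats.get(j, ()):
                canonical = min(rep, _revcomp(rep))
                planted_at.setdefault(canonical, []).append(
                    (pos, rep != canonical)
                )
                seq_parts.append(rep)
                pos += len(rep)
            junctions.append(pos)
            block = blocks_by_id[abs(sb)]
            genes = block.genes if sb > 0 else tuple(
                (g, -s) for g, s in reversed(block.genes)
            )
            for (gname, _), s in genes:
                gs = gene_seq[(gname, 0)] if s > 0 else _revcomp(
                    gene_seq[(gname, 0)]
                )
                kind = (
                    "tRNA" if gname.startswith("trn")
                    else "rRNA" if gname.startswith("rrn") else "protein"
                )
                layout.append((gname, kind, pos, pos + len(gs), s))
                seq_parts.append(gs)
                pos += len(gs)
        full = "".join(seq_parts)
        for canonical, occs in planted_at.items():
            for a in range(len(occs)):
                for b in range(a + 1, len(occs)):
                    (p1, f1), (p2, f2) = occs[a], occs[b]
                    orient = "direct" if f1 == f2 else "inverted"
                    repeats_here.append(
                        (p1, p2, cfg.repeat_length, orient)
                    )
        history.sequences[leaf] = full
        history.planted_repeats[leaf] = repeats_here
        history.block_junctions[leaf] = junctions
        history.feature_layout[leaf] = layout


def emit_genbank(history: SimulatedHistory, out_dir: str | Path) -> dict[str, Path]:
    """Write one minimal circular GenBank record per leaf.

    Records round-trip through :func:`mtpaleo.genome_io.read_genbank` and
    :func:`extract_gene_order` to the leaf's ground-truth gene order.
    """
    from Bio.Seq import Seq
    from Bio.SeqFeature import FeatureLocation, SeqFeature
    from Bio.SeqRecord import SeqRecord
    from Bio import SeqIO

    if not history.sequences:
        raise ValueError("history has no sequences; set emit_sequences=True")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}
    for leaf, seq in history.sequences.items():
        order = history.leaf_orders[leaf]
        record = SeqRecord(
            Seq(seq),
            id=leaf,
            name=leaf[:16],
            description=f"simulated mitochondrial genome of {leaf}",
        )
        record.annotations["molecule_type"] = "DNA"
        record.annotations["topology"] = "circular"
        for name, kind, s, e, strand in history.feature_layout[leaf]:
            ftype = {"tRNA": "tRNA", "rRNA": "rRNA"}.get(kind, "CDS")
            feat = SeqFeature(
                FeatureLocation(s, e, strand=strand),
                type=ftype,
                qualifiers={"gene": [name]},
            )
            record.features.append(feat)
        path = out_dir / f"{leaf}.gb"
        SeqIO.write(record, str(path), "genbank")
        paths[leaf] = path
    return paths
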