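"""Ancestral block arrangements on a rooted phylogeny.

Given one block arrangement per leaf and a rooted tree with a designated
outgroup, internal-node arrangements are inferred by collinearity rules:

* **case 1** — if a descendant leaf of the node is collinear (structural
  distance zero on shared block content) with the node's outside context
  (sibling state or outgroup), that arrangement is ancestral: structure
  shared across the split predates it.
* **case 2** — else, if a leaf of the node's earliest-diverging child clade
  is collinear with a leaf of another child clade, that shared arrangement
  is ancestral.
* **parsimony fallback** — else the descendant-leaf arrangement minimizing
  the summed structural distance to the child states and the context is
  chosen and flagged; exact ties are flagged ambiguous with all candidates
  listed.

Block *content* at each node is set by Dollo parsimony (a block can be
gained once, lost many times), so gains land on the stem of the clade where
the block first appears.  Branch events are then read off as the structural
scenario from each parent state to each child state.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import dendropy

from .rearrange import (
    RearrangeError,
    Scenario,
    reversal_distance,
    structural_distance,
)
from .synteny import BlockSequence

logger = logging.getLogger(__name__)

__all__ = [
    "Phylogeny",
    "AncestralStates",
    "EventSummary",
    "AncestorError",
    "read_newick",
    "reconstruct_ancestors",
    "infer_branch_events",
]


class AncestorError(ValueError):
    pass


@dataclass
class Phylogeny:
    """A rooted tree with unique leaf labels and a designated outgroup."""

    tree: dendropy.Tree
    outgroup: str

    def __post_init__(self) -> None:
        labels = [l.taxon.label for l in self.tree.leaf_node_iter()]
        if len(labels) != len(set(labels)):
            raise AncestorError("duplicate leaf labels in tree")
        if self.outgroup not in labels:
            raise AncestorError(f"outgroup {self.outgroup!r} not a leaf")
        root_children = self.tree.seed_node.child_nodes()
        og_parent_labels = {
            l.taxon.label
            for c in root_children
            if c.is_leaf()
            for l in [c]
        }
        if self.outgroup not in og_parent_labels:
            # accept an outgroup clade: the outgroup leaf must descend from
            # a child of the root
            for c in root_children:
                if self.outgroup in {l.taxon.label for l in c.leaf_iter()}:
                    break
            else:  # pragma: no cover
                raise AncestorError("outgroup must descend from the root")

    @property
    def leaves(self) -> list[str]:
        return [l.taxon.label for l in self.tree.leaf_node_iter()]

    def ingroup_root(self) -> dendropy.Node:
        """The root of the clade that excludes the outgroup."""
        candidates = [
            c
            for c in self.tree.seed_node.child_nodes()
            if self.outgroup not in {l.taxon.label for l in c.leaf_iter()}
        ]
        if len(candidates) != 1:
            raise AncestorError(
                "root must split the outgroup from a single ingroup clade"
            )
        return candidates[0]


def read_newick(
    path: str | Path, outgroup: str, allow_polytomy: bool = False
) -> Phylogeny:
    """Read a rooted Newick tree; polytomies are rejected by default."""
    try:
        tree = dendropy.Tree.get(
            path=str(path), schema="newick", rooting="force-rooted"
        )
    except Exception as exc:
        raise AncestorError(f"cannot parse Newick file {path}: {exc}") from exc
    for node in tree.preorder_node_iter():
        k = len(node.child_nodes())
        if k > 2 and not allow_polytomy:
            raise AncestorError(
                f"polytomy of degree {k} at node {node}; resolve the tree or "
                "pass allow_polytomy (child order then sets branch priority)"
            )
    return Phylogeny(tree=tree, outgroup=outgroup)


@dataclass
class AncestralStates:
    """Inferred arrangement and inference status per internal node."""

    states: dict[int, BlockSequence]  # node id -> arrangement
    status: dict[int, str]  # case1 | case2 | parsimony_fallback | ambiguous | leaf
    candidates: dict[int, list[BlockSequence]] = field(default_factory=dict)
    node_labels: dict[int, str] = field(default_factory=dict)

    def state_of(self, label: str) -> BlockSequence:
        for nid, lab in self.node_labels.items():
            if lab == label:
                return self.states[nid]
        raise KeyError(label)

    def has_ambiguity(self) -> bool:
        return any(s == "ambiguous" for s in self.status.values())


@dataclass
class EventSummary:
    branch_scenarios: dict[tuple[str, str], Scenario]
    totals: dict[str, int]
    grand_total: int
    cumulative_from_root: dict[str, int]

    def to_frame(self):
        import pandas as pd

        rows = [
            {
                "parent": pa,
                "child": ch,
                "steps": len(sc),
                **sc.counts(),
            }
            for (pa, ch), sc in self.branch_scenarios.items()
        ]
        return pd.DataFrame(rows)


# --------------------------------------------------------------------------
# reconstruction
# --------------------------------------------------------------------------


def _collinear(a: BlockSequence, b: BlockSequence) -> bool:
    """Zero structural distance restricted to shared block content."""
    shared = a.content() & b.content()
    if not shared:
        return False
    ra = [x for x in a.arrangement if abs(x) in shared]
    rb = [x for x in b.arrangement if abs(x) in shared]
    sa = BlockSequence(a.taxon_id, ra, a.circular)
    sb = BlockSequence(b.taxon_id, rb, b.circular)
    try:
        return reversal_distance(sa, sb) == 0
    except RearrangeError:
        d, _ = structural_distance(sa, sb)
        return d == 0


def _restrict(seq: BlockSequence, content: set[int], taxon_id: str) -> BlockSequence:
    arr = [x for x in seq.arrangement if abs(x) in content]
    return BlockSequence(taxon_id, arr, seq.circular)


def _dollo_content(
    node: dendropy.Node,
    leaf_content: dict[str, set[int]],
    outside_content: set[int],
) -> set[int]:
    """Blocks present at a node under Dollo parsimony: present iff seen in
    at least two of the directions (each child subtree; the outside)."""
    directions: list[set[int]] = []
    for c in node.child_nodes():
        sub = set()
        for l in c.leaf_iter():
            sub |= leaf_content[l.taxon.label]
        directions.append(sub)
    directions.append(outside_content)
    all_blocks = set().union(*directions)
    return {
        b for b in all_blocks if sum(b in d for d in directions) >= 2
    }


def reconstruct_ancestors(
    phylogeny: Phylogeny, leaves: Sequence[BlockSequence]
) -> AncestralStates:
    """Infer block arrangements at every internal ingroup node (post-order)."""
    by_taxon = {s.taxon_id: s for s in leaves}
    tree_leaves = set(phylogeny.leaves)
    data_leaves = set(by_taxon)
    if tree_leaves != data_leaves:
        diff = tree_leaves.symmetric_difference(data_leaves)
        raise AncestorError(f"tree/arrangement leaf mismatch: {sorted(diff)}")
    outgroup_state = by_taxon[phylogeny.outgroup]
    leaf_content = {t: s.content() for t, s in by_taxon.items()}

    states: dict[int, BlockSequence] = {}
    status: dict[int, str] = {}
    candidates: dict[int, list[BlockSequence]] = {}
    node_labels: dict[int, str] = {}

    ingroup_root = phylogeny.ingroup_root()
    counter = [0]

    def label_for(node: dendropy.Node) -> str:
        if node.is_leaf():
            return node.taxon.label
        counter[0] += 1
        return f"N{counter[0]}"

    def outside_leaves(node: dendropy.Node) -> list[str]:
        inside = {l.taxon.label for l in node.leaf_iter()}
        return [t for t in phylogeny.leaves if t not in inside]

    def context_state(node: dendropy.Node) -> BlockSequence:
        parent = node.parent_node
        if parent is not None:
            for sib in parent.child_nodes():
                if sib is node:
                    continue
                sid = id(sib)
                if sib.is_leaf():
                    return by_taxon[sib.taxon.label]
                if sid in states:
                    return states[sid]
        return outgroup_state

    for node in ingroup_root.postorder_iter():
        nid = id(node)
        if node.is_leaf():
            lab = node.taxon.label
            states[nid] = by_taxon[lab]
            status[nid] = "leaf"
            node_labels[nid] = lab
            continue
        lab = label_for(node)
        node_labels[nid] = lab
        ctx = context_state(node)
        outside = set()
        for t in outside_leaves(node):
            outside |= leaf_content[t]
        content = _dollo_content(node, leaf_content, outside)
        desc = [l.taxon.label for l in node.leaf_iter()]

        def coverage(t: str) -> int:
            return len(leaf_content[t] & content)

        chosen: BlockSequence | None = None
        chosen_status = ""
        # case 1: a descendant leaf collinear with the outside context;
        # among qualifying leaves prefer the one covering most of the
        # node's (Dollo) block content
        case1 = [t for t in desc if _collinear(by_taxon[t], ctx)]
        if case1:
            chosen = by_taxon[max(case1, key=lambda t: (coverage(t), -desc.index(t)))]
            chosen_status = "case1"
        # case 2: earliest-diverging child clade leaf collinear with a leaf
        # of another child clade
        if chosen is None:
            children = node.child_nodes()
            first = children[0]
            rest = children[1:]
            case2: list[str] = []
            for t1 in (l.taxon.label for l in first.leaf_iter()):
                for other in rest:
                    for l2 in other.leaf_iter():
                        t2 = l2.taxon.label
                        if _collinear(by_taxon[t1], by_taxon[t2]):
                            # both members carry the shared ancestral
                            # structure; keep both as representatives
                            case2.extend((t1, t2))
            if case2:
                chosen = by_taxon[
                    max(case2, key=lambda t: (coverage(t), -desc.index(t)))
                ]
                chosen_status = "case2"
        if chosen is not None:
            states[nid] = _restrict(chosen, content & chosen.content(), lab)
            status[nid] = chosen_status
            continue
        # parsimony fallback over descendant-leaf arrangements
        child_states = [
            states[id(c)] for c in node.child_nodes() if id(c) in states
        ]
        best: list[tuple[int, str, BlockSequence]] = []
        for t in desc:
            cand = _restrict(by_taxon[t], content & leaf_content[t], lab)
            cost = 0
            try:
                for ref in child_states + [ctx]:
                    d, _ = structural_distance(cand, ref)
                    cost += d
            except RearrangeError:
                continue
            best.append((cost, -coverage(t), t, cand))
        if not best:
            raise AncestorError(f"no viable candidate arrangement at {lab}")
        best.sort(key=lambda x: (x[0], x[1], x[2]))
        min_cost = best[0][0]
        winners = [b for b in best if b[0] == min_cost]
        if len(winners) > 1 and not all(
            _same_state(w[3], winners[0][3]) for w in winners[1:]
        ):
            states[nid] = winners[0][3]
            status[nid] = "ambiguous"
            candidates[nid] = [w[3] for w in winners]
            logger.warning(
                "%s: %d tied candidate arrangements; flagged ambiguous",
                lab,
                len(winners),
            )
        else:
            states[nid] = winners[0][3]
            status[nid] = "parsimony_fallback"
            logger.info("%s: parsimony fallback (cost %d)", lab, min_cost)

    return AncestralStates(
        states=states,
        status=status,
        candidates=candidates,
        node_labels=node_labels,
    )


def _same_state(a: BlockSequence, b: BlockSequence) -> bool:
    from .rearrange import same_arrangement

    return a.content() == b.content() and same_arrangement(
        a.arrangement, b.arrangement, a.circular
    )


# --------------------------------------------------------------------------
# branch events
# --------------------------------------------------------------------------


def infer_branch_events(
    phylogeny: Phylogeny, states: AncestralStates, allow_ambiguous: bool = False
) -> EventSummary:
    """Structural scenario on every ingroup branch parent -> child.

    The ingroup root state stands for the common ancestor; no state is
    inferred above the outgroup split, so the outgroup branch carries no
    events.  Per-taxon cumulative step counts from the root are included.
    """
    if states.has_ambiguity() and not allow_ambiguous:
        raise AncestorError(
            "ambiguous nodes present; resolve candidates or pass "
            "allow_ambiguous=True to use the first candidate"
        )
    ingroup_root = phylogeny.ingroup_root()
    scenarios: dict[tuple[str, str], Scenario] = {}
    totals = {"reversion": 0, "gene_gain": 0, "gene_loss": 0,
              "block_duplication": 0}
    cumulative: dict[str, int] = {}

    def walk(node: dendropy.Node, steps_so_far: int) -> None:
        parent_state = states.states[id(node)]
        parent_label = states.node_labels[id(node)]
        for child in node.child_nodes():
            child_state = states.states[id(child)]
            child_label = states.node_labels[id(child)]
            d, scen = structural_distance(parent_state, child_state)
            scenarios[(parent_label, child_label)] = scen
            for k, v in scen.counts().items():
                totals[k] += v
            if child.is_leaf():
                cumulative[child_label] = steps_so_far + d
            else:
                walk(child, steps_so_far + d)

    if ingroup_root.is_leaf():
        lab = states.node_labels[id(ingroup_root)]
        cumulative[lab] = 0
    else:
        walk(ingroup_root, 0)
    grand = sum(totals.values())
    return EventSummary(
        branch_scenarios=scenarios,
        totals=totals,
        grand_total=grand,
        cumulative_from_root=cumulative,
    )
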