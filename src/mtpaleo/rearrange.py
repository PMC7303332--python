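"""Structural distances and event scenarios between block arrangements.

The elementary operation of plant-mt structural evolution modelled here is
the *reversion* (inversion) of a contiguous run of blocks, typically
mediated by inverted repeats at its endpoints.  For arrangements with
identical block content the minimum number of reversions is the classic
signed reversal distance, computed exactly from the breakpoint graph:

    d = (n + 1) - c + h + f

with ``c`` the number of cycles, ``h`` the number of hurdles (unoriented
components that do not separate other unoriented components on the circle
of graph positions) and ``f`` = 1 for a fortress (an odd number of hurdles,
all of them superhurdles).  A breadth-first-search oracle
(:func:`reversal_distance_bfs`, exact but exponential) certifies the
formula in the test-suite.

Content differences are charged one step per event: a block private to one
genome is a gene gain/loss (direction-dependent), and a repeated occurrence
run of duplicated blocks collapses to a single *block duplication* step.
The total is the structural distance; it is symmetric by construction.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from functools import lru_cache
from math import factorial
from typing import Sequence

import numpy as np
import pandas as pd

from .synteny import BlockSequence

logger = logging.getLogger(__name__)

__all__ = [
    "Event",
    "Scenario",
    "DistanceMatrix",
    "RearrangeError",
    "reversal_distance",
    "reversal_distance_bfs",
    "reversal_distance_table",
    "sort_by_reversals",
    "structural_distance",
    "pairwise_matrix",
    "apply_scenario",
    "same_arrangement",
]


class RearrangeError(ValueError):
    pass


class ContentMismatchError(RearrangeError):
    """Raised by reversal-only routines on unequal block content; use
    structural_distance for arrangements that differ in content."""


# --------------------------------------------------------------------------
# events and scenarios
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class Event:
    kind: str  # reversion | gene_gain | gene_loss | block_duplication
    span: tuple[int, ...]  # signed block ids involved, at application time
    index: int  # position in the (linearized) arrangement where applied
    note: str = ""

    def __post_init__(self) -> None:
        if self.kind not in {"reversion", "gene_gain", "gene_loss",
                             "block_duplication"}:
            raise ValueError(f"unknown event kind {self.kind!r}")
        if not self.span:
            raise ValueError("event span must be nonempty")


@dataclass
class Scenario:
    source: str
    target: str
    events: list[Event] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.events)

    def counts(self) -> dict[str, int]:
        out = {"reversion": 0, "gene_gain": 0, "gene_loss": 0,
               "block_duplication": 0}
        for e in self.events:
            out[e.kind] += 1
        return out


@dataclass
class DistanceMatrix:
    taxa: list[str]
    steps: np.ndarray  # square, symmetric, zero diagonal

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.steps, index=self.taxa, columns=self.taxa)

    def __getitem__(self, pair: tuple[str, str]) -> int:
        i, j = self.taxa.index(pair[0]), self.taxa.index(pair[1])
        return int(self.steps[i, j])


# --------------------------------------------------------------------------
# arrangement helpers
# --------------------------------------------------------------------------


def _reflect(arr: Sequence[int]) -> list[int]:
    return [-x for x in reversed(arr)]


def same_arrangement(a: Sequence[int], b: Sequence[int], circular: bool) -> bool:
    """Equality of signed arrangements; circular ones match up to rotation
    and reflection (both describe the same molecule)."""
    a, b = list(a), list(b)
    if len(a) != len(b):
        return False
    if not circular:
        return a == b or a == _reflect(b)
    if len(a) == 0:
        return True
    for cand in (b, _reflect(b)):
        for r in range(len(cand)):
            if a == cand[r:] + cand[:r]:
                return True
    return False


def _anchor_linearize(arr: Sequence[int], anchor: int) -> list[int]:
    """Rotate/reflect a circular arrangement so +anchor comes first."""
    arr = list(arr)
    hits = [i for i, x in enumerate(arr) if abs(x) == anchor]
    if len(hits) != 1:
        raise RearrangeError(
            f"anchor block {anchor} occurs {len(hits)} times; need exactly one"
        )
    i = hits[0]
    if arr[i] < 0:
        arr = _reflect(arr)
        i = len(arr) - 1 - i
    return arr[i:] + arr[:i]


def _choose_anchor(a: Sequence[int], b: Sequence[int]) -> int | None:
    """Smallest block id occurring exactly once in both arrangements."""
    from collections import Counter

    ca = Counter(abs(x) for x in a)
    cb = Counter(abs(x) for x in b)
    common = [k for k in ca if ca[k] == 1 and cb.get(k) == 1]
    return min(common) if common else None


def _to_permutation(a: Sequence[int], b: Sequence[int]) -> tuple[int, ...]:
    """Relabel so that b becomes the identity; returns a as a signed
    permutation of 1..n.  Requires identical single-occurrence content."""
    if sorted(abs(x) for x in a) != sorted(abs(x) for x in b):
        raise ContentMismatchError(
            "arrangements differ in block content; use structural_distance"
        )
    if len({abs(x) for x in a}) != len(a):
        raise ContentMismatchError(
            "duplicated block occurrences; use structural_distance"
        )
    index = {abs(x): (i + 1, 1 if x > 0 else -1) for i, x in enumerate(b)}
    perm = []
    for x in a:
        i, s = index[abs(x)]
        perm.append(i * s * (1 if x > 0 else -1))
    return tuple(perm)


# --------------------------------------------------------------------------
# Hannenhalli-Pevzner distance on a signed permutation (identity target)
# --------------------------------------------------------------------------


class _UnionFind:
    def __init__(self, n: int) -> None:
        self.parent = list(range(n))

    def find(self, x: int) -> int:
        while self.parent[x] != x:
            self.parent[x] = self.parent[self.parent[x]]
            x = self.parent[x]
        return x

    def union(self, a: int, b: int) -> None:
        ra, rb = self.find(a), self.find(b)
        if ra != rb:
            self.parent[ra] = rb


def _hp_distance(perm: Sequence[int]) -> int:
    n = len(perm)
    if n == 0:
        return 0
    # doubled representation: +x -> (2x-1, 2x); -x -> (2x, 2x-1); framed 0..2n+1
    seq = [0]
    for x in perm:
        v = abs(x)
        seq.extend((2 * v - 1, 2 * v) if x > 0 else (2 * v, 2 * v - 1))
    seq.append(2 * n + 1)
    pos = {v: i for i, v in enumerate(seq)}

    uf = _UnionFind(2 * n + 2)
    for k in range(n + 1):  # black edges join consecutive positions 2k, 2k+1
        uf.union(seq[2 * k], seq[2 * k + 1])
    for i in range(n + 1):  # gray edges join values 2i, 2i+1
        uf.union(2 * i, 2 * i + 1)
    cycles = {uf.find(v) for v in range(2 * n + 2)}
    c = len(cycles)

    # gray edges of nontrivial cycles
    edges = []  # (left_pos, right_pos, oriented, cycle_root)
    for i in range(n + 1):
        p, q = pos[2 * i], pos[2 * i + 1]
        l, r = (p, q) if p < q else (q, p)
        if r == l + 1:
            continue  # adjacency (trivial cycle)
        edges.append((l, r, (r - l) % 2 == 0, uf.find(2 * i)))
    if not edges:
        return n + 1 - c

    # components: cycles whose gray edges interleave
    roots = sorted({e[3] for e in edges})
    comp = _UnionFind(len(roots))
    rindex = {root: i for i, root in enumerate(roots)}
    for i in range(len(edges)):
        l1, r1, _, c1 = edges[i]
        for j in range(i + 1, len(edges)):
            l2, r2, _, c2 = edges[j]
            if l1 < l2 < r1 < r2 or l2 < l1 < r2 < r1:
                comp.union(rindex[c1], rindex[c2])

    positions: dict[int, list[int]] = {}
    oriented: dict[int, bool] = {}
    for l, r, ori, root in edges:
        cid = comp.find(rindex[root])
        positions.setdefault(cid, []).extend((l, r))
        oriented[cid] = oriented.get(cid, False) or ori
    unoriented = [cid for cid in positions if not oriented[cid]]
    if not unoriented:
        return n + 1 - c

    h, f = _hurdles_and_fortress(positions, unoriented)
    return n + 1 - c + h + f


def _compressed_circular(labels: list[int]) -> list[int]:
    out: list[int] = []
    for lab in labels:
        if not out or out[-1] != lab:
            out.append(lab)
    if len(out) > 1 and out[0] == out[-1]:
        out.pop()
    return out


def _hurdle_set(run_list: list[int]) -> set[int]:
    from collections import Counter

    counts = Counter(run_list)
    return {lab for lab, k in counts.items() if k == 1}


def _hurdles_and_fortress(
    positions: dict[int, list[int]], unoriented: list[int]
) -> tuple[int, int]:
    """Count hurdles and detect a fortress.

    A hurdle is an unoriented component whose graph positions form a single
    contiguous arc once all positions are read around the circle, i.e. it
    does not separate other unoriented components.  A hurdle is a
    superhurdle if removing it would promote a non-hurdle unoriented
    component into a hurdle; a fortress has an odd number of hurdles, all of
    them superhurdles.
    """
    order = sorted((p, cid) for cid in unoriented for p in positions[cid])
    labels = [cid for _, cid in order]
    runs = _compressed_circular(labels)
    hurdles = _hurdle_set(runs)
    h = len(hurdles)
    f = 0
    if h % 2 == 1:
        all_super = True
        for hd in hurdles:
            reduced = _compressed_circular([lab for lab in labels if lab != hd])
            promoted = _hurdle_set(reduced) - hurdles
            if not promoted:
                all_super = False
                break
        if all_super:
            f = 1
    return h, f


# --------------------------------------------------------------------------
# public distance API
# --------------------------------------------------------------------------


def _pair_to_linear(
    a: BlockSequence, b: BlockSequence
) -> tuple[list[int], list[int]]:
    """Reduce a pair of same-content arrangements to the linear problem."""
    A, B = list(a.arrangement), list(b.arrangement)
    if a.circular != b.circular:
        raise RearrangeError("cannot compare circular with linear arrangement")
    if a.circular and len(A) > 1:
        anchor = _choose_anchor(A, B)
        if anchor is None:
            raise RearrangeError("no single-copy common block to anchor on")
        A = _anchor_linearize(A, anchor)
        B = _anchor_linearize(B, anchor)
        # with the anchor pinned first the rest is a linear problem
        return A[1:], B[1:]
    return A, B


def reversal_distance(a: BlockSequence, b: BlockSequence) -> int:
    """Minimum number of reversions between same-content arrangements.

    Circular arrangements are anchored on the smallest common single-copy
    block and reduced to the linear problem.
    """
    la, lb = _pair_to_linear(a, b)
    return _hp_distance(_to_permutation(la, lb))


def reversal_distance_bfs(
    a: BlockSequence, b: BlockSequence, max_blocks: int = 10
) -> int:
    """Exact reversal distance by bidirectional breadth-first search.

    Independent of the breakpoint-graph formula; exponential, hence refused
    above ``max_blocks`` blocks.  Used to certify :func:`reversal_distance`.
    """
    la, lb = _pair_to_linear(a, b)
    if len(la) > max_blocks:
        raise RearrangeError(
            f"{len(la)} blocks exceeds BFS limit of {max_blocks}"
        )
    perm = _to_permutation(la, lb)
    return _bfs_distance(perm)


def _reversal_moves(n: int) -> list[tuple[int, int]]:
    return [(i, j) for i in range(n) for j in range(i, n)]


def _apply_reversal(state: tuple[int, ...], i: int, j: int) -> tuple[int, ...]:
    return state[:i] + tuple(-x for x in reversed(state[i : j + 1])) + state[j + 1 :]


def _bfs_distance(perm: tuple[int, ...]) -> int:
    n = len(perm)
    ident = tuple(range(1, n + 1))
    if perm == ident:
        return 0
    moves = _reversal_moves(n)
    front_a = {perm: 0}
    front_b = {ident: 0}
    seen_a, seen_b = dict(front_a), dict(front_b)
    depth = 0
    while True:
        depth += 1
        # expand the smaller frontier
        if len(front_a) > len(front_b):
            front_a, front_b = front_b, front_a
            seen_a, seen_b = seen_b, seen_a
        nxt: dict[tuple[int, ...], int] = {}
        for state, d in front_a.items():
            for i, j in moves:
                s2 = _apply_reversal(state, i, j)
                if s2 in seen_a:
                    continue
                if s2 in seen_b:
                    return d + 1 + seen_b[s2]
                nxt[s2] = d + 1
        seen_a.update(nxt)
        front_a = nxt
        if not front_a:
            raise RuntimeError("BFS frontier exhausted without meeting")


# --------------------------------------------------------------------------
# exhaustive distance table (vectorized BFS from the identity, n <= 8)
# --------------------------------------------------------------------------


@lru_cache(maxsize=4)
def reversal_distance_table(n: int) -> np.ndarray:
    """Distance-to-identity for every signed permutation of 1..n (n <= 8).

    Breadth-first search over the full state space, vectorized with numpy;
    the returned array is indexed by :func:`perm_rank`.  Serves as an
    exhaustive oracle for the breakpoint-graph formula.
    """
    if not (1 <= n <= 8):
        raise RearrangeError("distance table supported for 1 <= n <= 8")
    size = factorial(n) * (1 << n)
    dist = np.full(size, 255, dtype=np.uint8)
    ident = np.arange(1, n + 1, dtype=np.int8)[None, :]
    dist[perm_rank(ident)[0]] = 0
    frontier = ident
    d = 0
    moves = _reversal_moves(n)
    while frontier.shape[0]:
        d += 1
        nxt_parts = []
        for i, j in moves:
            cand = frontier.copy()
            cand[:, i : j + 1] = -cand[:, j : None if i == 0 else i - 1 : -1]
            r = perm_rank(cand)
            fresh = dist[r] == 255
            if fresh.any():
                dist[r[fresh]] = d
                nxt_parts.append(cand[fresh])
        if not nxt_parts:
            break
        frontier = np.concatenate(nxt_parts)
        # states can re-enter via different moves at the same level; dedupe
        r = perm_rank(frontier)
        _, keep = np.unique(r, return_index=True)
        frontier = frontier[keep]
    return dist


def perm_rank(perms: np.ndarray) -> np.ndarray:
    """Rank signed permutations (rows, values +-1..n) into 0..n!*2^n-1."""
    perms = np.asarray(perms)
    m, n = perms.shape
    a = np.abs(perms) - 1
    rank = np.zeros(m, dtype=np.int64)
    for i in range(n - 1):
        smaller_after = (a[:, i + 1 :] < a[:, i : i + 1]).sum(axis=1)
        rank = rank * (n - i) + smaller_after
    signbits = ((perms < 0) << np.arange(n)).sum(axis=1)
    return rank * (1 << n) + signbits


# --------------------------------------------------------------------------
# explicit optimal sorting
# --------------------------------------------------------------------------


def sort_by_reversals(a: BlockSequence, b: BlockSequence) -> Scenario:
    """One optimal reversal scenario transforming ``a`` into ``b``.

    Greedy descent on the exact distance: at each step the applied reversal
    is the first distance-reducing one ordered by left endpoint, then span
    length — deterministic and of length ``reversal_distance(a, b)``.
    """
    la, lb = _pair_to_linear(a, b)
    perm = list(_to_permutation(la, lb))
    events: list[Event] = []
    offset = 1 if (a.circular and len(a.arrangement) > 1) else 0
    cur = list(la)
    d = _hp_distance(tuple(perm))
    n = len(perm)
    while d > 0:
        found = False
        # candidate reversals ordered by left endpoint, then span length
        for i in range(n):
            for j in range(i, n):
                cand = tuple(_apply_reversal(tuple(perm), i, j))
                if _hp_distance(cand) == d - 1:
                    events.append(
                        Event(
                            kind="reversion",
                            span=tuple(cur[i : j + 1]),
                            index=i + offset,
                        )
                    )
                    perm = list(cand)
                    cur[i : j + 1] = [-x for x in reversed(cur[i : j + 1])]
                    d -= 1
                    found = True
                    break
            if found:
                break
        if not found:  # pragma: no cover - would indicate a distance bug
            raise RuntimeError("no distance-reducing reversal found")
    return Scenario(source=a.taxon_id, target=b.taxon_id, events=events)


# --------------------------------------------------------------------------
# structural distance: reversions + gains/losses/duplications
# --------------------------------------------------------------------------


def _adjacency_pairs(arr: Sequence[int], circular: bool) -> set[tuple[int, int]]:
    pairs = set()
    n = len(arr)
    rng = range(n) if circular and n > 1 else range(n - 1)
    for i in rng:
        x, y = arr[i], arr[(i + 1) % n]
        pairs.add(min((x, y), (-y, -x)))
    return pairs


def _deletion_candidates(
    W: list[int], other: Sequence[int], circular: bool, cap: int = 64
) -> list[list[int]]:
    """Candidate sets of occurrence indices to delete so that each
    over-represented id keeps ``count-in-other`` copies.  Exhaustive over
    per-id keep-choices up to ``cap`` combinations, else a single greedy
    (context-scored) choice."""
    from collections import Counter
    from itertools import combinations, product
    from math import comb

    cw = Counter(abs(x) for x in W)
    co = Counter(abs(x) for x in other)
    collapse_ids = sorted(
        v for v in cw if cw[v] > co.get(v, 0) >= 1
    )
    if not collapse_ids:
        return [[]]
    occ = {v: [i for i, x in enumerate(W) if abs(x) == v] for v in collapse_ids}
    n_combo = 1
    for v in collapse_ids:
        n_combo *= comb(cw[v], cw[v] - co[v])
    if n_combo <= cap:
        per_id = [
            list(combinations(occ[v], cw[v] - co[v])) for v in collapse_ids
        ]
        return [sorted(sum(map(list, combo), [])) for combo in product(*per_id)]

    # greedy fallback: keep the occurrence whose flanking context matches
    other_adj = _adjacency_pairs(other, circular)
    n = len(W)

    def score(i: int) -> int:
        s = 0
        left = min((W[i - 1], W[i]), (-W[i], -W[i - 1]))
        right = min((W[i], W[(i + 1) % n]), (-W[(i + 1) % n], -W[i]))
        if i > 0 or circular:
            s += left in other_adj
        if i < n - 1 or circular:
            s += right in other_adj
        return s

    to_delete: list[int] = []
    for v in collapse_ids:
        ranked = sorted(occ[v], key=lambda i: (-score(i), i))
        to_delete.extend(sorted(ranked[co[v] :]))
    return [sorted(to_delete)]


def _rev_estimate(a: Sequence[int], b: Sequence[int]) -> int:
    """Reversal distance between the parts of a and b with matching copy
    numbers (equal-count duplicates matched by the optimizing relabeler)."""
    from collections import Counter

    ca, cb = Counter(abs(x) for x in a), Counter(abs(x) for x in b)
    ok = {v for v in ca if ca[v] == cb.get(v)}
    ra = [x for x in a if abs(x) in ok]
    rb = [x for x in b if abs(x) in ok]
    ra2, rb2, _ = _relabel_shared_copies(ra, rb)
    try:
        return _hp_distance(_to_permutation(ra2, rb2))
    except ContentMismatchError:  # pragma: no cover
        return 0


def _collapse_duplicates(
    W: list[int], other: Sequence[int], circular: bool
) -> tuple[list[int], list[Event]]:
    """Delete extra occurrences of ids over-represented in ``W`` relative to
    ``other``.  Among the possible keep-choices the one minimizing
    (#contiguous deletion runs + residual reversal distance) is taken, so a
    duplication whose copies were later torn apart by reversions still
    collapses as a single event.  Contiguous deletions merge into one
    block_duplication event."""
    best: tuple[int, list[int]] | None = None
    for to_delete in _deletion_candidates(W, other, circular):
        if not to_delete:
            return W, []
        groups_n = 1 + sum(
            1
            for i, j in zip(to_delete, to_delete[1:])
            if j != i + 1
        )
        trial = [x for i, x in enumerate(W) if i not in set(to_delete)]
        cost = groups_n + _rev_estimate(trial, other)
        if best is None or cost < best[0]:
            best = (cost, to_delete)
    assert best is not None
    to_delete = best[1]
    groups: list[list[int]] = [[to_delete[0]]]
    for i in to_delete[1:]:
        if i == groups[-1][-1] + 1:
            groups[-1].append(i)
        else:
            groups.append([i])
    events: list[Event] = []
    removed_before = 0
    out = list(W)
    for grp in groups:
        start = grp[0] - removed_before
        span = tuple(out[start : start + len(grp)])
        events.append(
            Event("block_duplication", span=span, index=start, note="collapse")
        )
        del out[start : start + len(grp)]
        removed_before += len(grp)
    return out, events


def _relabel_shared_copies(
    A: list[int], B: list[int]
) -> tuple[list[int], list[int], dict[int, int]]:
    """Ids occurring the same number (>1) of times in both sides are given
    fresh ids per occurrence so the reversal machinery sees a permutation.

    The copy correspondence between the two sides is chosen to minimize the
    resulting reversal distance (exhaustive over per-id copy permutations,
    capped at 64 combinations; occurrence order beyond that).  Returns the
    back-mapping from fresh ids to original ids."""
    from collections import Counter
    from itertools import permutations, product
    from math import factorial

    ca, cb = Counter(abs(x) for x in A), Counter(abs(x) for x in B)
    dup = sorted(v for v in ca if ca[v] > 1 and cb.get(v) == ca[v])
    if not dup:
        return A, B, {}
    nxt = max(list(ca) + list(cb)) + 1
    back: dict[int, int] = {}
    fresh_for: dict[int, list[int]] = {}
    for v in dup:
        fresh_for[v] = list(range(nxt, nxt + ca[v]))
        for f in fresh_for[v]:
            back[f] = v
        nxt += ca[v]

    def relabel(arr: list[int], perm_by_id: dict[int, tuple[int, ...]]) -> list[int]:
        k: dict[int, int] = {}
        out = []
        for x in arr:
            v = abs(x)
            if v in fresh_for:
                j = k.get(v, 0)
                k[v] = j + 1
                f = fresh_for[v][perm_by_id[v][j]]
                out.append(f if x > 0 else -f)
            else:
                out.append(x)
        return out

    ident = {v: tuple(range(ca[v])) for v in dup}
    A2 = relabel(A, ident)
    n_combo = 1
    for v in dup:
        n_combo *= factorial(ca[v])
    if n_combo > 64:
        return A2, relabel(B, ident), back
    best: tuple[int, list[int]] | None = None
    for combo in product(*(permutations(range(ca[v])) for v in dup)):
        perm_by_id = dict(zip(dup, combo))
        B2 = relabel(B, perm_by_id)
        try:
            d = _hp_distance(_to_permutation(A2, B2))
        except ContentMismatchError:  # pragma: no cover
            continue
        if best is None or d < best[0]:
            best = (d, B2)
    assert best is not None
    return A2, best[1], back


def _restore_span(span: tuple[int, ...], back: dict[int, int]) -> tuple[int, ...]:
    out = []
    for x in span:
        v = back.get(abs(x), abs(x))
        out.append(v if x > 0 else -v)
    return tuple(out)


def structural_distance(
    a: BlockSequence, b: BlockSequence
) -> tuple[int, Scenario]:
    """Minimum structural steps from ``a`` to ``b`` and an explicit scenario.

    Steps = (blocks private to ``a``: gene losses) + (blocks private to
    ``b``: gene gains) + (collapsed duplication runs, either side) +
    the signed reversal distance on the shared, deduplicated content.
    Every step costs 1; the total is symmetric in ``a`` and ``b``.
    """
    if a.circular != b.circular:
        raise RearrangeError("cannot compare circular with linear arrangement")
    circular = a.circular
    A, B = list(a.arrangement), list(b.arrangement)
    shared = {abs(x) for x in A} & {abs(x) for x in B}
    if not shared:
        raise RearrangeError(
            f"no common structure between {a.taxon_id} and {b.taxon_id}"
        )
    anchor = _choose_anchor(A, B)
    if circular and len(A) > 1 and anchor is not None:
        A = _anchor_linearize(A, anchor)
        B = _anchor_linearize(B, anchor)

    events: list[Event] = []
    W = list(A)
    # 1. losses: ids private to a (all occurrences removed, one step per id)
    lost = {abs(x) for x in A} - {abs(x) for x in B}
    while True:
        hit = next((i for i, x in enumerate(W) if abs(x) in lost), None)
        if hit is None:
            break
        v = abs(W[hit])
        occs = tuple(x for x in W if abs(x) == v)
        events.append(Event("gene_loss", span=occs, index=hit))
        W = [x for x in W if abs(x) != v]
        lost.discard(v)
    # 2. collapse duplicated occurrences on the source side
    W, collapse_events = _collapse_duplicates(W, B, circular)
    events.extend(collapse_events)
    # 3. collapse the target side (these replay as expansions later)
    Bc, expand_events = _collapse_duplicates(
        [x for x in B if abs(x) in shared], W, circular
    )
    # 4. reversions on the shared, deduplicated content
    Wr, Br, back = _relabel_shared_copies(W, Bc)
    rev = sort_by_reversals(
        BlockSequence("src", Wr, circular=False),
        BlockSequence("tgt", Br, circular=False),
    )
    for e in rev.events:
        events.append(
            Event("reversion", span=_restore_span(e.span, back), index=e.index)
        )
    W = list(Bc)
    # 5. expansions: re-insert duplicated runs of the target side
    for e in reversed(expand_events):
        span = list(e.span)
        W[e.index : e.index] = span
        events.append(
            Event("block_duplication", span=tuple(span), index=e.index,
                  note="expand")
        )
    # 6. gains: ids private to b, inserted at their positions in B
    gained_ids = sorted(
        {abs(x) for x in B} - shared,
        key=lambda v: next(i for i, x in enumerate(B) if abs(x) == v),
    )
    for v in gained_ids:
        occs = [(i, x) for i, x in enumerate(B) if abs(x) == v]
        # insert all occurrences (one step per id), ascending position
        for i, x in occs:
            W.insert(_insert_index(W, B, i), x)
        events.append(Event("gene_gain", span=tuple(x for _, x in occs),
                            index=_index_of(B, v)))
    if not same_arrangement(W, B, circular):
        raise RuntimeError(
            "internal error: scenario replay does not reach the target"
        )
    scen = Scenario(source=a.taxon_id, target=b.taxon_id, events=events)
    return len(events), scen


def _index_of(B: Sequence[int], v: int) -> int:
    return next(i for i, x in enumerate(B) if abs(x) == v)


def _insert_index(W: Sequence[int], B: Sequence[int], pos_in_b: int) -> int:
    """Index in W at which B[pos_in_b] should be inserted so that W's
    relative order matches B for the elements already present."""
    present = {abs(x) for x in W}
    count = sum(1 for x in B[:pos_in_b] if abs(x) in present)
    return count


def apply_scenario(
    arrangement: Sequence[int], scenario: Scenario, circular: bool,
    anchor: int | None = None,
) -> list[int]:
    """Replay a scenario's events on an arrangement (linearized if circular).

    The replayed result must match the scenario's target up to rotation and
    reflection for circular arrangements; tests assert this for simulated
    pairs.
    """
    W = list(arrangement)
    if circular and len(W) > 1 and anchor is not None:
        W = _anchor_linearize(W, anchor)
    for e in scenario.events:
        if e.kind == "gene_loss":
            v = abs(e.span[0])
            W = [x for x in W if abs(x) != v]
        elif e.kind == "gene_gain":
            for x in e.span:
                W.insert(min(e.index, len(W)), x)
        elif e.kind == "reversion":
            i, L = e.index, len(e.span)
            seg = W[i : i + L]
            if seg != list(e.span):
                raise RearrangeError(
                    f"reversion span mismatch at {i}: {seg} != {list(e.span)}"
                )
            W[i : i + L] = [-x for x in reversed(seg)]
        elif e.kind == "block_duplication":
            if e.note == "collapse":
                i, L = e.index, len(e.span)
                if W[i : i + L] != list(e.span):
                    raise RearrangeError("duplication span mismatch")
                del W[i : i + L]
            else:
                W[e.index : e.index] = list(e.span)
    return W


def pairwise_matrix(seqs: Sequence[BlockSequence]) -> DistanceMatrix:
    """Structural steps between every pair of arrangements (symmetric)."""
    if len(seqs) < 2:
        raise RearrangeError("need at least two arrangements")
    n = len(seqs)
    steps = np.zeros((n, n), dtype=int)
    for i in range(n):
        for j in range(i + 1, n):
            d, _ = structural_distance(seqs[i], seqs[j])
            steps[i, j] = steps[j, i] = d
    return DistanceMatrix(taxa=[s.taxon_id for s in seqs], steps=steps)
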