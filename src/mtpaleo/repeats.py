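"""Exact repeat pairs, repeat families, and block-boundary association.

Plant mt genomes rearrange largely through recombination between repeated
sequences: direct repeats resolve deletions/duplications and inverted
repeats reverse the region between them.  This module finds all maximal
exact repeated pairs (direct and inverted, with circular wrap), groups
homologous repeats across taxa by alignment identity, and quantifies the
association between repeat locations and syntenic block boundaries with a
rotation permutation test.

The finder is k-mer seed-and-extend: every ``min_len``-mer present more
than once (or matching on the reverse complement) seeds a candidate pair
which is extended maximally in both directions on the circle; pairs are
deduplicated on their maximal coordinates.  Exactness is the contract —
the test-suite certifies the finder against an independent quadratic scan.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np

logger = logging.getLogger(__name__)

__all__ = [
    "RepeatPair",
    "RepeatFamily",
    "EnrichmentResult",
    "RepeatError",
    "find_repeats",
    "cluster_repeat_families",
    "boundary_enrichment",
]

_COMP = str.maketrans("ACGTN", "TGCAN")


def _revcomp(s: str) -> str:
    return s.translate(_COMP)[::-1]


class RepeatError(ValueError):
    pass


@dataclass(frozen=True, order=True)
class RepeatPair:
    taxon_id: str
    pos1: int
    pos2: int
    length: int
    orientation: str  # direct | inverted

    def sequence(self, genome: str) -> str:
        n = len(genome)
        s = self.pos1
        if s + self.length <= n:
            return genome[s : s + self.length]
        return genome[s:] + genome[: (s + self.length) % n]


@dataclass
class RepeatFamily:
    family_id: int
    members: list[tuple[str, RepeatPair]]  # (taxon, pair)
    representative: str

    @property
    def total_length(self) -> int:
        return sum(p.length for _, p in self.members)


@dataclass
class EnrichmentResult:
    observed: int
    null_mean: float
    null_sd: float
    p_value: float
    n_perm: int
    seed: int
    window: int


# --------------------------------------------------------------------------
# maximal exact repeats
# --------------------------------------------------------------------------


def _char_at(seq: str, i: int, circular: bool) -> str | None:
    n = len(seq)
    if circular:
        return seq[i % n]
    if 0 <= i < n:
        return seq[i]
    return None


def _match(a: str | None, b: str | None) -> bool:
    return a is not None and b is not None and a == b and a != "N"


def find_repeats(
    seq: str, min_len: int = 50, circular: bool = True, taxon_id: str = ""
) -> list[RepeatPair]:
    """All maximal exact repeated pairs of length >= ``min_len``.

    Both orientations are searched; ``N`` never matches; for circular
    sequences matches may cross the origin (positions are reported mod the
    sequence length).  Output is sorted by (pos1, pos2).  ``min_len`` below
    8 is refused: the output size explodes on random sequence.
    """
    if min_len < 8:
        raise RepeatError("min_len < 8 refused (output explosion guard)")
    seq = seq.upper()
    n = len(seq)
    if n < min_len:
        return []
    k = min_len
    ext = seq + seq[: k - 1] if circular else seq
    limit = n if circular else n - k + 1

    kmer_pos: dict[str, list[int]] = {}
    for i in range(limit):
        mer = ext[i : i + k]
        if "N" in mer:
            continue
        kmer_pos.setdefault(mer, []).append(i)

    found: set[tuple[int, int, int, str]] = set()

    def extend(p1: int, p2: int, orientation: str) -> tuple[int, int, int]:
        """Maximal extension of a seeded match; returns (start1, start2, len)
        with starts of the two copies (for inverted: start of each copy on
        the forward strand)."""
        if orientation == "direct":
            L = k
            # left extension
            while True:
                a = _char_at(seq, p1 - 1, circular)
                b = _char_at(seq, p2 - 1, circular)
                if L >= n or not _match(a, b):
                    break
                # tandem self-overlap guard: stop at full period
                p1 -= 1
                p2 -= 1
                L += 1
            while True:
                a = _char_at(seq, p1 + L, circular)
                b = _char_at(seq, p2 + L, circular)
                if L >= n or not _match(a, b):
                    break
                L += 1
            return p1 % n if circular else p1, p2 % n if circular else p2, L
        # inverted: copy1 forward at p1, copy2 is revcomp of seq at p2..p2+L
        L = k
        while True:  # extend left of copy1 == right of copy2
            a = _char_at(seq, p1 - 1, circular)
            b = _char_at(seq, p2 + L, circular)
            if L >= n or a is None or b is None or a == "N" or b == "N":
                break
            if a != b.translate(_COMP):
                break
            p1 -= 1
            L += 1
        while True:  # extend right of copy1 == left of copy2
            a = _char_at(seq, p1 + L, circular)
            b = _char_at(seq, p2 - 1, circular)
            if L >= n or a is None or b is None or a == "N" or b == "N":
                break
            if a != b.translate(_COMP):
                break
            p2 -= 1
            L += 1
        return p1 % n if circular else p1, p2 % n if circular else p2, L

    # direct pairs
    for mer, plist in kmer_pos.items():
        if len(plist) < 2:
            continue
        for ai in range(len(plist)):
            for bi in range(ai + 1, len(plist)):
                p1, p2 = plist[ai] % n, plist[bi] % n
                if p1 == p2:
                    continue
                s1, s2, L = extend(p1, p2, "direct")
                if L < min_len:
                    continue
                a, b = sorted((s1, s2))
                if (s2 - s1) % n == 0:
                    continue
                found.add((a, b, L, "direct"))

    # inverted pairs: k-mers of the reverse complement strand
    rc = _revcomp(seq)
    ext_rc = rc + rc[: k - 1] if circular else rc
    for i in range(limit):
        mer = ext_rc[i : i + k]
        if mer not in kmer_pos:
            continue
        # position of this rc-kmer's copy on the forward strand
        p2 = (n - (i + k)) % n if circular else n - (i + k)
        if p2 < 0:
            continue
        for p1 in kmer_pos[mer]:
            p1 = p1 % n
            s1, s2, L = extend(p1, p2, "inverted")
            if L < min_len:
                continue
            a, b = sorted((s1 % n, s2 % n))
            if a == b:
                continue  # palindrome matching itself is not a pair
            found.add((a, b, L, "inverted"))

    pairs = [
        RepeatPair(taxon_id=taxon_id, pos1=a, pos2=b, length=L, orientation=o)
        for a, b, L, o in found
    ]
    pairs.sort(key=lambda p: (p.pos1, p.pos2, p.orientation, p.length))
    return pairs


# --------------------------------------------------------------------------
# repeat families
# --------------------------------------------------------------------------


def _identity(a: str, b: str) -> float:
    """Alignment identity over the shorter sequence (best orientation)."""
    import edlib

    if len(a) > len(b):
        a, b = b, a
    best = 0.0
    for query in (a, _revcomp(a)):
        res = edlib.align(query, b, mode="HW", task="distance")
        d = res["editDistance"]
        if d >= 0:
            best = max(best, 1.0 - d / len(a))
    return best


def cluster_repeat_families(
    pairs_by_taxon: Mapping[str, Sequence[RepeatPair]],
    genomes: Mapping[str, str],
    identity: float = 0.9,
) -> list[RepeatFamily]:
    """Single-linkage clustering of repeat occurrences across taxa.

    Two repeats join the same family when their sequences align at >=
    ``identity`` over the shorter one (either orientation).  Families are
    ordered by total member length, largest first; the representative is
    the longest member sequence.
    """
    entries: list[tuple[str, RepeatPair, str]] = []
    for taxon, plist in pairs_by_taxon.items():
        for p in plist:
            entries.append((taxon, p, p.sequence(genomes[taxon])))
    m = len(entries)
    parent = list(range(m))

    def find(x: int) -> int:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for i in range(m):
        for j in range(i + 1, m):
            if find(i) == find(j):
                continue
            if _identity(entries[i][2], entries[j][2]) >= identity:
                parent[find(i)] = find(j)

    groups: dict[int, list[int]] = {}
    for i in range(m):
        groups.setdefault(find(i), []).append(i)
    families = []
    for fid, idxs in enumerate(
        sorted(
            groups.values(),
            key=lambda g: -sum(entries[i][1].length for i in g),
        ),
        start=1,
    ):
        rep = max((entries[i][2] for i in idxs), key=len)
        families.append(
            RepeatFamily(
                family_id=fid,
                members=[(entries[i][0], entries[i][1]) for i in idxs],
                representative=rep,
            )
        )
    return families


# --------------------------------------------------------------------------
# boundary association
# --------------------------------------------------------------------------


def _min_circular_distance(point: int, boundaries: np.ndarray, n: int) -> int:
    d = np.abs(boundaries - point)
    return int(np.minimum(d, n - d).min())


def _occurrence_positions(pairs: Iterable[RepeatPair]) -> list[tuple[int, int]]:
    occ = []
    for p in pairs:
        occ.append((p.pos1, p.length))
        occ.append((p.pos2, p.length))
    return occ


def boundary_enrichment(
    pairs: Sequence[RepeatPair],
    boundaries: Sequence[int],
    genome_length: int,
    window: int = 1000,
    n_perm: int = 9999,
    seed: int = 0,
) -> EnrichmentResult:
    """Permutation test: are repeat occurrences near block boundaries?

    ``observed`` counts repeat occurrences whose interval comes within
    ``window`` bp of any boundary (circular distance).  The null rotates
    each occurrence independently by a uniform random offset around the
    circle, ``n_perm`` times.  p = (1 + #null >= observed) / (1 + n_perm).
    """
    if not boundaries:
        raise RepeatError("no block boundaries supplied")
    bnd = np.asarray(sorted(boundaries), dtype=np.int64)
    occs = _occurrence_positions(pairs)
    if not occs:
        raise RepeatError("no repeat occurrences supplied")
    n = genome_length

    def near_mask(pos: np.ndarray, lens: np.ndarray) -> np.ndarray:
        """Whether each occurrence interval [p, p+L) on the circle comes
        within ``window`` of a boundary; vectorized, arrays broadcast."""
        lo = pos % n
        hi = (pos + lens) % n
        b = bnd.reshape((1,) * lo.ndim + (-1,))
        lo_e, hi_e = lo[..., None], hi[..., None]
        dl = np.abs(b - lo_e)
        dl = np.minimum(dl, n - dl).min(axis=-1)
        dh = np.abs(b - hi_e)
        dh = np.minimum(dh, n - dh).min(axis=-1)
        plain = (b >= lo_e) & (b <= hi_e)
        wrap = (b >= lo_e) | (b <= hi_e)
        inside = np.where(lo_e <= hi_e, plain, wrap).any(axis=-1)
        return inside | (np.minimum(dl, dh) <= window)

    pos = np.array([p for p, _ in occs], dtype=np.int64)
    lens = np.array([L for _, L in occs], dtype=np.int64)
    observed = int(near_mask(pos, lens).sum())
    rng = np.random.default_rng(seed)
    null = np.empty(n_perm, dtype=np.int64)
    chunk = 512
    for start in range(0, n_perm, chunk):
        m = min(chunk, n_perm - start)
        shifts = rng.integers(0, n, size=(m, len(pos)))
        null[start : start + m] = near_mask(
            (pos[None, :] + shifts) % n, lens[None, :]
        ).sum(axis=1)
    p_value = (1 + int((null >= observed).sum())) / (1 + n_perm)
    return EnrichmentResult(
        observed=observed,
        null_mean=float(null.mean()),
        null_sd=float(null.std()),
        p_value=float(p_value),
        n_perm=n_perm,
        seed=seed,
        window=window,
    )
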