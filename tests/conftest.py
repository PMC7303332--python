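"""Shared fixtures: synthetic GenBank records and simulated histories."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")

COMP = str.maketrans("ACGTN", "TGCAN")


def revcomp(s: str) -> str:
    return s.translate(COMP)[::-1]


def random_dna(rng: np.random.Generator, n: int) -> str:
    return "".join(np.array(list("ACGT"))[rng.integers(0, 4, n)])


def make_genbank(path, name, seq, features, circular=True):
    """Write a minimal GenBank record; features are
    (gene, type, [(start, end, strand), ...], pseudo) tuples with 0-based
    half-open coordinates (multiple segments become a join location)."""
    from Bio.Seq import Seq
    from Bio.SeqFeature import (CompoundLocation, FeatureLocation,
                                SeqFeature)
    from Bio.SeqRecord import SeqRecord
    from Bio import SeqIO

    record = SeqRecord(Seq(seq), id=name, name=name[:16], description="")
    record.annotations["molecule_type"] = "DNA"
    record.annotations["topology"] = "circular" if circular else "linear"
    for gene, ftype, segments, pseudo in features:
        locs = [FeatureLocation(s, e, strand=st) for s, e, st in segments]
        loc = locs[0] if len(locs) == 1 else CompoundLocation(locs)
        quals = {"gene": [gene]}
        if pseudo:
            quals["pseudo"] = [""]
        record.features.append(SeqFeature(loc, type=ftype, qualifiers=quals))
    SeqIO.write(record, str(path), "genbank")
    return path


@pytest.fixture(scope="session")
def default_history():
    from mtpaleo.simulate import SimulationConfig, simulate_history

    return simulate_history(SimulationConfig(seed=42))


@pytest.fixture(scope="session")
def sequence_history():
    from mtpaleo.simulate import SimulationConfig, simulate_history

    return simulate_history(
        SimulationConfig(seed=17, emit_sequences=True,
                         mean_events_per_branch=2.0)
    )


# --------------------------------------------------------------------------
# independent quadratic repeat oracle (offset / anti-diagonal scan)
# --------------------------------------------------------------------------


def brute_force_repeats(seq: str, min_len: int, circular: bool) -> set:
    """All maximal exact repeat pairs by scanning every offset (direct) and
    every anti-diagonal (inverted); independent of the k-mer finder."""
    n = len(seq)
    out: set = set()
    arr = np.frombuffer(seq.encode(), dtype=np.uint8)
    valid = arr != ord("N")
    comp = np.frombuffer(seq.translate(COMP).encode(), dtype=np.uint8)

    def circular_runs(mask):
        if mask.all():
            return None  # degenerate: fully periodic
        idx = np.flatnonzero(~mask)
        k = len(idx)
        for t in range(k):
            start = (idx[t] + 1) % n
            end = idx[(t + 1) % k]
            yield start, int((end - start) % n)

    # direct pairs at every offset
    for d in range(1, n):
        if circular:
            m = (arr == np.roll(arr, -d)) & valid & np.roll(valid, -d)
            runs = circular_runs(m)
            if runs is None:
                continue
            for start, L in runs:
                if L >= min_len:
                    x, y = sorted((start, (start + d) % n))
                    if x != y:
                        out.add((x, y, L, "direct"))
        else:
            length = n - d
            m = (arr[:length] == arr[d:]) & valid[:length] & valid[d:]
            i = 0
            while i < length:
                if m[i]:
                    j = i
                    while j < length and m[j]:
                        j += 1
                    if j - i >= min_len:
                        out.add((i, i + d, j - i, "direct"))
                    i = j
                else:
                    i += 1
    # inverted pairs on every anti-diagonal a + b = c
    if circular:
        for c in range(n):
            a_idx = np.arange(n)
            b_idx = (c - a_idx) % n
            m = (arr == comp[b_idx]) & valid & valid[b_idx]
            runs = circular_runs(m)
            if runs is None:
                continue
            for start, L in runs:
                if L >= min_len:
                    a, b = start, (c - (start + L - 1)) % n
                    x, y = sorted((a, b))
                    if x != y:
                        out.add((x, y, L, "inverted"))
    else:
        for c in range(0, 2 * n - 1):
            a_lo, a_hi = max(0, c - n + 1), min(n - 1, c)
            a_idx = np.arange(a_lo, a_hi + 1)
            b_idx = c - a_idx
            m = (arr[a_idx] == comp[b_idx]) & valid[a_idx] & valid[b_idx]
            i, ln = 0, len(a_idx)
            while i < ln:
                if m[i]:
                    j = i
                    while j < ln and m[j]:
                        j += 1
                    L = j - i
                    if L >= min_len:
                        a = int(a_idx[i])
                        b = c - int(a_idx[j - 1])
                        x, y = sorted((a, b))
                        if x != y:
                            out.add((x, y, L, "inverted"))
                    i = j
                else:
                    i += 1
    return out
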