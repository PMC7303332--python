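"""Reversal distance (formula vs BFS), sorting, structural distance."""

from __future__ import annotations

import itertools

import numpy as np
import pytest

from mtpaleo.rearrange import (
    ContentMismatchError,
    RearrangeError,
    apply_scenario,
    pairwise_matrix,
    perm_rank,
    reversal_distance,
    reversal_distance_bfs,
    reversal_distance_table,
    same_arrangement,
    sort_by_reversals,
    structural_distance,
)
from mtpaleo.synteny import BlockSequence


def lin(tax, arr):
    return BlockSequence(tax, list(arr), circular=False)


def circ(tax, arr):
    return BlockSequence(tax, list(arr), circular=True)


def random_signed_perm(rng, n):
    return [int((i + 1) * s) for i, s in
            zip(rng.permutation(n), rng.choice([1, -1], n))]


class TestReversalDistance:
    def test_identity_zero(self):
        assert reversal_distance(lin("a", [1, -2, 3]), lin("b", [1, -2, 3])) == 0

    def test_single_flip(self):
        assert reversal_distance(lin("a", [1, -2, 3]), lin("b", [1, 2, 3])) == 1

    def test_transposition_needs_three(self):
        # (+2,+1) -> (+1,+2) cannot be done in fewer than 3 reversals
        assert reversal_distance(lin("a", [2, 1]), lin("b", [1, 2])) == 3

    def test_sign_flip_single_element(self):
        assert reversal_distance_bfs(lin("a", [-1]), lin("b", [1])) == 1

    def test_content_mismatch_redirects(self):
        with pytest.raises(ContentMismatchError):
            reversal_distance(lin("a", [1, 2]), lin("b", [1, 3]))

    def test_exhaustive_agreement_three_blocks(self):
        table = reversal_distance_table(3)
        ident = lin("id", [1, 2, 3])
        for perm_abs in itertools.permutations((1, 2, 3)):
            for signs in itertools.product((1, -1), repeat=3):
                arr = [a * s for a, s in zip(perm_abs, signs)]
                d_formula = reversal_distance(lin("x", arr), ident)
                d_bfs = reversal_distance_bfs(lin("x", arr), ident)
                r = perm_rank(np.array([arr], dtype=np.int8))[0]
                assert d_formula == d_bfs == table[r]

    @pytest.mark.parametrize("n", [4, 5, 6])
    def test_formula_vs_exhaustive_table(self, n):
        table = reversal_distance_table(n)
        rng = np.random.default_rng(n)
        ident = lin("id", list(range(1, n + 1)))
        for _ in range(200):
            arr = random_signed_perm(rng, n)
            r = perm_rank(np.array([arr], dtype=np.int8))[0]
            assert reversal_distance(lin("x", arr), ident) == table[r]

    def test_circular_reduction(self):
        # one reversal on the circle, anchored at block 1
        a = circ("a", [1, -3, -2, 4])
        b = circ("b", [1, 2, 3, 4])
        assert reversal_distance(a, b) == 1
        # rotated representation of the same molecule: distance unchanged
        a2 = circ("a", [-2, 4, 1, -3])
        assert reversal_distance(a2, b) == 1

    def test_metric_properties_random_triples(self):
        rng = np.random.default_rng(0)
        for _ in range(60):
            n = int(rng.integers(2, 8))
            x, y, z = (lin(t, random_signed_perm(rng, n)) for t in "xyz")
            dxy = reversal_distance(x, y)
            dyx = reversal_distance(y, x)
            assert dxy == dyx
            assert reversal_distance(x, x) == 0
            assert dxy <= reversal_distance(x, z) + reversal_distance(z, y)

    def test_bfs_refuses_large_input(self):
        big = lin("a", list(range(1, 13)))
        with pytest.raises(RearrangeError, match="exceeds"):
            reversal_distance_bfs(big, lin("b", list(range(1, 13))))


class TestSortByReversals:
    def test_single_flip_names_span(self):
        scen = sort_by_reversals(lin("a", [1, -2, 3]), lin("b", [1, 2, 3]))
        assert len(scen) == 1
        assert scen.events[0].kind == "reversion"
        assert scen.events[0].span == (-2,)

    def test_empty_for_equal(self):
        scen = sort_by_reversals(lin("a", [2, -1]), lin("b", [2, -1]))
        assert len(scen) == 0

    def test_replay_random_pairs(self):
        rng = np.random.default_rng(1)
        for _ in range(200):
            n = int(rng.integers(2, 9))
            a, b = random_signed_perm(rng, n), random_signed_perm(rng, n)
            A, B = lin("a", a), lin("b", b)
            scen = sort_by_reversals(A, B)
            assert len(scen) == reversal_distance(A, B)
            assert apply_scenario(a, scen, circular=False) == b

    def test_deterministic(self):
        a, b = [3, -1, 2, -4], [1, 2, 3, 4]
        s1 = sort_by_reversals(lin("a", a), lin("b", b))
        s2 = sort_by_reversals(lin("a", a), lin("b", b))
        assert s1.events == s2.events


class TestStructuralDistance:
    def test_equal_content_reduces_to_reversals(self):
        a, b = lin("a", [1, -3, -2, 4]), lin("b", [1, 2, 3, 4])
        d, scen = structural_distance(a, b)
        assert d == reversal_distance(a, b)
        assert all(e.kind == "reversion" for e in scen.events)

    def test_single_gain(self):
        d, scen = structural_distance(lin("a", [1, 2, 3]),
                                      lin("b", [1, 2, 4, 3]))
        assert d == 1
        assert scen.counts() == {"reversion": 0, "gene_gain": 1,
                                 "gene_loss": 0, "block_duplication": 0}

    def test_single_loss_symmetry(self):
        d_ab, _ = structural_distance(lin("a", [1, 2, 4, 3]),
                                      lin("b", [1, 2, 3]))
        d_ba, _ = structural_distance(lin("b", [1, 2, 3]),
                                      lin("a", [1, 2, 4, 3]))
        assert d_ab == d_ba == 1

    def test_tandem_duplicated_run_is_one_step(self):
        a = lin("a", [1, 2, 3, 4, 2, 3, 4, 5])
        b = lin("b", [1, 2, 3, 4, 5])
        d, scen = structural_distance(a, b)
        assert d == 1
        assert scen.events[0].kind == "block_duplication"
        assert scen.events[0].span == (2, 3, 4)

    def test_duplication_torn_by_reversion_still_two_steps(self):
        # duplicate [2,3], then reverse a span cutting through the copies:
        # the minimum scenario still has two events
        a = lin("a", [1, 2, 3, 2, 3, 4])
        b = lin("b", [1, 2, -3, -2, 3, 4])
        d, _ = structural_distance(b, a)
        assert d <= 2

    def test_no_shared_blocks_error(self):
        with pytest.raises(RearrangeError, match="common"):
            structural_distance(lin("a", [1, 2]), lin("b", [3, 4]))

    def test_symmetry_random(self):
        rng = np.random.default_rng(2)
        for _ in range(50):
            n = int(rng.integers(3, 8))
            a = random_signed_perm(rng, n)
            b = random_signed_perm(rng, n)
            # random content perturbations
            if rng.random() < 0.5 and len(a) > 2:
                a = a[:-1]
            if rng.random() < 0.3:
                b = b + [n + 1]
            A, B = lin("a", a), lin("b", b)
            d1, _ = structural_distance(A, B)
            d2, _ = structural_distance(B, A)
            assert d1 == d2

    def test_simulated_reversal_count(self):
        # k non-overlapping reversions, no content change -> distance k
        from mtpaleo.simulate import SimulationConfig, simulate_history

        h = simulate_history(
            SimulationConfig(seed=4, kind_weights=(1, 0, 0, 0))
        )
        for leaf, state in h.states.items():
            k = sum(
                len(evs)
                for clade, evs in h.branch_events.items()
                if leaf in clade
            )
            d, _ = structural_distance(h.root_state, state)
            assert d == k


class TestPairwiseMatrix:
    def test_symmetric_zero_diagonal(self):
        rng = np.random.default_rng(3)
        seqs = [lin(f"t{i}", random_signed_perm(rng, 6)) for i in range(4)]
        m = pairwise_matrix(seqs)
        assert (m.steps == m.steps.T).all()
        assert (np.diag(m.steps) == 0).all()

    def test_identical_taxa_zero_off_diagonal(self):
        m = pairwise_matrix([lin("a", [1, 2, 3]), lin("b", [1, 2, 3])])
        assert m[("a", "b")] == 0

    def test_needs_two(self):
        with pytest.raises(RearrangeError):
            pairwise_matrix([lin("a", [1])])


class TestSameArrangement:
    def test_circular_rotation_and_reflection(self):
        assert same_arrangement([1, 2, 3], [2, 3, 1], circular=True)
        assert same_arrangement([1, 2, 3], [-3, -2, -1], circular=True)
        assert not same_arrangement([1, 2, 3], [1, 3, 2], circular=True)

    def test_linear_reflection_only(self):
        assert same_arrangement([1, 2], [-2, -1], circular=False)
        assert not same_arrangement([1, 2], [2, 1], circular=False)
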