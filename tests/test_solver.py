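"""The zero-run observability algorithm on the worked examples, plus
its structural invariants."""

import math

import numpy as np
import pytest
from hypothesis import assume, given, settings
from hypothesis import strategies as st

from boolobs.attractors import Attractor, AttractorSet
from boolobs.oracle import window_distinguishes
from boolobs.solver import (
    RunTable,
    coverage_gap,
    enumerate_combinations,
    find_zero_runs,
    min_required_length,
    min_window_length,
    pair_xor_matrix,
    prune_runs,
    recover_windows,
    solve,
)

EX2_FIRST_BISTATE = [
    "111101", "000111", "101011", "111010", "010110", "101100",
]
EX2_SECOND_BISTATE = [
    "111110", "001111", "110100", "110001", "001010", "111011",
]
EX3_MATRICES = [
    ["010110", "001010", "001011", "010010"],
    ["010110", "001010", "001011", "101010"],
    ["010110", "001010", "110101", "010010"],
    ["010110", "001010", "110101", "101010"],
]


def as_rows(strings):
    return np.array([list(s) for s in strings], dtype=np.uint8)


def first_combination(aset):
    return next(iter(enumerate_combinations(aset)))


class TestEnumerateCombinations:
    def test_example3_combinations_in_printed_order(self, ex3):
        combos = list(enumerate_combinations(ex3))
        assert len(combos) == ex3.n_combinations == 4
        for combo, expected in zip(combos, EX3_MATRICES):
            assert (combo.matrix == as_rows(expected)).all()
        assert [c.phase_choice for c in combos] == [
            (0, 0, 0, 0), (0, 0, 0, 1), (0, 0, 1, 0), (0, 0, 1, 1)
        ]

    def test_all_singletons_yield_one_stacked_combination(self, ex2_first):
        combos = list(enumerate_combinations(ex2_first))
        assert len(combos) == 1
        assert combos[0].index == 1
        assert (combos[0].matrix == np.stack([a.states[0] for a in ex2_first])).all()

    def test_periods_two_and_three_give_six_unique_pairs(self):
        aset = AttractorSet(
            [
                Attractor([[0, 0, 0], [0, 0, 1]]),
                Attractor([[0, 1, 0], [0, 1, 1], [1, 0, 0]]),
            ]
        )
        combos = list(enumerate_combinations(aset))
        assert len(combos) == 6
        pairs = {(c.phase_choice[0], c.phase_choice[1]) for c in combos}
        assert pairs == {(i, j) for i in range(2) for j in range(3)}


class TestPairXor:
    def test_first_example_matrix(self, ex2_first):
        bi = pair_xor_matrix(first_combination(ex2_first))
        assert (bi.rows == as_rows(EX2_FIRST_BISTATE)).all()
        assert bi.pair_index == ((1, 2), (1, 3), (1, 4), (2, 3), (2, 4), (3, 4))

    def test_second_example_matrix(self, ex2_second):
        bi = pair_xor_matrix(first_combination(ex2_second))
        assert (bi.rows == as_rows(EX2_SECOND_BISTATE)).all()

    def test_identical_rows_give_zero_row(self):
        from boolobs.solver import PhaseCombination

        A = PhaseCombination(as_rows(["0110", "0110"]), (0, 0), 1)
        bi = pair_xor_matrix(A)
        assert (bi.rows == 0).all()


class TestZeroRuns:
    def test_first_example_runs_and_coverage(self, ex2_first):
        bi = pair_xor_matrix(first_combination(ex2_first))
        rt = find_zero_runs(bi, threshold=2)
        assert rt.runs == ((1, 3), (5, 6))
        assert rt.covered == frozenset({1, 2, 3, 5, 6})
        assert coverage_gap(rt, 6) == {4}

    def test_second_example_runs_in_row_order(self, ex2_second):
        bi = pair_xor_matrix(first_combination(ex2_second))
        rt = find_zero_runs(bi, threshold=2)
        assert rt.runs == ((1, 2), (5, 6), (3, 5), (1, 2))
        assert coverage_gap(rt, 6) == set()

    def test_all_ones_matrix_has_no_runs(self):
        from boolobs.solver import PairDifferenceMatrix

        bi = PairDifferenceMatrix(np.ones((3, 7), dtype=np.uint8), ((1, 2), (1, 3), (2, 3)))
        rt = find_zero_runs(bi, threshold=1)
        assert rt.runs == ()
        assert coverage_gap(rt, 7) == set(range(1, 8))


class TestPruneRuns:
    def test_sort_same_start_dedup_and_containment(self):
        rt = RunTable(((1, 5), (4, 7), (3, 9), (3, 6), (2, 8)), frozenset(range(1, 10)), 2)
        pruned = prune_runs(rt).pruned
        # [3,6] loses to [3,9] on shared start; [4,7] is inside [3,9]
        assert pruned == ((1, 5), (2, 8), (3, 9))

    def test_second_example_pruned_list(self, ex2_second):
        bi = pair_xor_matrix(first_combination(ex2_second))
        rt = prune_runs(find_zero_runs(bi, threshold=2))
        assert rt.pruned == ((1, 2), (3, 5), (5, 6))

    def test_contained_run_removed(self):
        rt = RunTable(((1, 4), (2, 3)), frozenset(range(1, 5)), 1)
        assert prune_runs(rt).pruned == ((1, 4),)

    def test_pruned_starts_and_ends_strictly_increase(self, ex3):
        for combo in enumerate_combinations(ex3):
            rt = find_zero_runs(pair_xor_matrix(combo), 2)
            pruned = prune_runs(rt).pruned
            starts = [s for s, _ in pruned]
            ends = [e for _, e in pruned]
            assert starts == sorted(set(starts)) and ends == sorted(set(ends))


class TestMinWindowLength:
    def test_adjacent_run_formula_on_second_example(self):
        rt = RunTable((), frozenset(range(1, 7)), 2, pruned=((1, 2), (3, 5), (5, 6)))
        assert min_window_length(rt, m=4) == 2

    def test_two_long_overlapping_runs(self):
        rt = RunTable((), frozenset(range(1, 7)), 2, pruned=((1, 5), (2, 6)))
        assert min_window_length(rt, m=4) == 6

    def test_single_spanning_run_is_infeasible(self):
        rt = RunTable((), frozenset(range(1, 7)), 2, pruned=((1, 6),))
        assert min_window_length(rt, m=4) == math.inf

    def test_requires_pruning_first(self):
        with pytest.raises(ValueError, match="prune"):
            min_window_length(RunTable((), frozenset(), 2), m=4)


class TestSolve:
    def test_example3_per_combination_minima(self, ex3):
        res = solve(ex3, exhaustive=True)
        assert res.per_combination == (4, 6, 3, 2)
        assert res.min_length == 2
        assert res.feasible

    def test_seven_gene_set_has_window_on_genes_3_and_4(self, seven_gene):
        res = solve(seven_gene, exhaustive=True)
        assert res.min_length == 2
        assert any(w[1:] == (3, 4) for w in res.windows)

    def test_drosophila_unique_window(self, drosophila):
        res = solve(drosophila)
        assert res.min_length == 22
        assert res.windows == ((1, 3, 24),)

    def test_single_attractor_needs_nothing(self):
        res = solve(AttractorSet([Attractor([[0, 1, 1]])]))
        assert res.min_length == 0 and res.feasible

    def test_empty_set_rejected(self):
        with pytest.raises(ValueError):
            AttractorSet([])

    def test_reported_windows_are_sound(self, ex3, seven_gene):
        for aset in (ex3, seven_gene):
            res = solve(aset, exhaustive=True)
            combos = {c.index: c for c in enumerate_combinations(aset)}
            for cid, start, end in res.windows:
                assert window_distinguishes(combos[cid], start, end - start + 1)


class TestRecoverWindows:
    def test_first_example_achievers(self, ex2_first):
        assert recover_windows(first_combination(ex2_first), 2) == [(3, 4), (4, 5)]

    def test_second_example_achievers(self, ex2_second):
        assert (2, 3) in recover_windows(first_combination(ex2_second), 2)

    def test_identical_rows_never_distinguished(self):
        from boolobs.solver import PhaseCombination

        A = PhaseCombination(as_rows(["0101", "0101"]), (0, 0), 1)
        for w in range(1, 5):
            assert recover_windows(A, w) == []


# ---------------------------------------------------------------------------
# invariants on random instances


@st.composite
def attractor_sets(draw):
    n = draw(st.integers(3, 9))
    periods = draw(st.lists(st.integers(1, 3), min_size=2, max_size=4))
    total = sum(periods)
    assume(2**n >= total)
    codes = draw(
        st.lists(st.integers(0, 2**n - 1), min_size=total, max_size=total, unique=True)
    )
    states = [[(c >> (n - 1 - i)) & 1 for i in range(n)] for c in codes]
    groups, at = [], 0
    for p in periods:
        groups.append(states[at : at + p])
        at += p
    return AttractorSet(Attractor(g) for g in groups)


@settings(max_examples=120, derandomize=True, deadline=None)
@given(attractor_sets())
def test_lower_bound_and_mode_agreement(aset):
    """Feasible answers respect ceil(log2 m), and the early-stop scan
    agrees with the exhaustive one."""
    early = solve(aset)
    full = solve(aset, exhaustive=True)
    assert early.min_length == full.min_length
    assert early.min_length >= min_required_length(aset.m)
    assert min(v for v in full.per_combination if math.isfinite(v)) == full.min_length


@settings(max_examples=80, derandomize=True, deadline=None)
@given(attractor_sets(), st.randoms(use_true_random=False))
def test_invariance_under_permutation_and_column_flips(aset, pyrandom):
    """Reordering attractors or flipping a column's polarity in every
    state leaves the pairwise XOR structure, hence the answer, alone."""
    base = solve(aset).min_length
    order = list(range(aset.m))
    pyrandom.shuffle(order)
    permuted = AttractorSet(aset[i] for i in order)
    assert solve(permuted).min_length == base
    col = pyrandom.randrange(aset.n)
    mask = np.zeros(aset.n, dtype=np.uint8)
    mask[col] = 1
    flipped = AttractorSet(Attractor(a.states ^ mask) for a in aset)
    assert solve(flipped).min_length == base


@settings(max_examples=80, derandomize=True, deadline=None)
@given(attractor_sets(), st.integers(1, 4), st.integers(0, 2**20 - 1))
def test_monotone_under_column_appending(aset, extra, bits):
    """Extra observed genes can only help: appending columns never
    increases the minimal window length."""
    base = solve(aset).min_length
    rng = np.random.default_rng(bits)
    wide = AttractorSet(
        Attractor(
            np.hstack(
                [a.states, rng.integers(0, 2, size=(a.period, extra), dtype=np.uint8)]
            )
        )
        for a in aset
    )
    assert solve(wide).min_length <= base
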