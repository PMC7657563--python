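"""Tests for CRT window pooling (DNA Sudoku) and 2D grid pooling."""

import itertools
import math

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from poolscreen import (
    PUBLISHED_WINDOWS,
    SampleStatusVector,
    SudokuDesign,
    grid_layout,
    place_positives,
    run_grid2d,
    run_sudoku,
    select_windows,
    sudoku_assign,
    sudoku_decode,
)
from poolscreen.nonadaptive import _greedy_extend


class TestWindowSelection:
    @pytest.mark.parametrize("n", [96, 384, 1536])
    def test_published_sets_returned_for_presets(self, n):
        w = len(PUBLISHED_WINDOWS[n])
        assert tuple(select_windows(n, w)) == PUBLISHED_WINDOWS[n]

    def test_prefix_for_smaller_weights(self):
        assert select_windows(96, 2) == [10, 11]
        assert select_windows(384, 4) == [20, 21, 23, 29]

    @pytest.mark.parametrize("n", [384, 1536])
    def test_greedy_scan_reproduces_larger_preset_sets(self, n):
        """The greedy co-prime scan alone recovers the 384/1536 sets."""
        w = len(PUBLISHED_WINDOWS[n])
        assert tuple(_greedy_extend(n, [], w)) == PUBLISHED_WINDOWS[n]

    def test_greedy_extension_beyond_published_weight(self):
        ws = select_windows(96, 8)
        assert ws[:6] == list(PUBLISHED_WINDOWS[96])
        for a, b in itertools.combinations(ws, 2):
            assert math.gcd(a, b) == 1

    @given(st.integers(20, 2000), st.integers(2, 8))
    @settings(max_examples=60, derandomize=True)
    def test_windows_exceed_sqrt_and_are_coprime(self, n, w):
        ws = select_windows(n, w)
        assert len(ws) == w
        assert all(x * x > n for x in ws)
        for a, b in itertools.combinations(ws, 2):
            assert math.gcd(a, b) == 1


class TestSudokuAssignment:
    def test_total_pools_and_weight_membership(self):
        design = sudoku_assign(96, [10, 11])
        assert len(design.pools) == 21
        membership = {}
        for pool in design.pools:
            for m in pool.members:
                membership.setdefault(m, []).append(pool.label)
        assert all(len(v) == 2 for v in membership.values())
        assert membership[78] == ["W1-8", "W2-1"]

    @pytest.mark.parametrize("n", [96, 384, 1536])
    def test_crt_pairwise_overlap_at_most_one(self, n):
        """Any two samples co-occur in at most one pool.

        Co-occurrence in two windows requires the index difference to be a
        multiple of both, i.e. of their lcm; co-prime windows > sqrt(N)
        make every pairwise lcm exceed N.
        """
        ws = PUBLISHED_WINDOWS[n]
        assert min(a * b // math.gcd(a, b)
                   for a, b in itertools.combinations(ws, 2)) >= n

    def test_crt_overlap_exhaustive_small(self):
        design = sudoku_assign(96, select_windows(96, 6))
        shared = {}
        for pool in design.pools:
            for a, b in itertools.combinations(pool.members, 2):
                shared[(a, b)] = shared.get((a, b), 0) + 1
        assert max(shared.values()) == 1


class TestSudokuDecode:
    def _results(self, n, windows, positives):
        design = SudokuDesign(n, tuple(windows))
        results = {}
        for i, wi in enumerate(design.windows, start=1):
            for r in range(wi):
                results[(i, r)] = any(p % wi == r for p in positives)
        return design, results

    def test_single_positive_unambiguous(self):
        design, results = self._results(96, (10, 11), {42})
        dec = sudoku_decode(results, design)
        assert dec.candidates == {42} and not dec.ambiguous

    def test_two_positives_with_weight_two_collide(self):
        design, results = self._results(96, (10, 11), {27, 78})
        dec = sudoku_decode(results, design)
        assert dec.candidates == {27, 38, 67, 78}
        assert dec.ambiguous
        assert dec.retest_indices == (27, 38, 67, 78)

    def test_all_negative_pools(self):
        design, results = self._results(96, (10, 11), set())
        dec = sudoku_decode(results, design)
        assert dec.candidates == frozenset() and not dec.ambiguous

    def test_missing_pool_result_rejected(self):
        design, results = self._results(96, (10, 11), {1})
        del results[(1, 0)]
        with pytest.raises(KeyError):
            sudoku_decode(results, design)

    @given(st.integers(0, 400), st.data())
    @settings(max_examples=80, derandomize=True)
    def test_guarantee_up_to_weight_minus_one(self, seed, data):
        """k <= w-1 positives always decode exactly and unambiguously."""
        w = data.draw(st.integers(2, 5))
        k = data.draw(st.integers(0, w - 1))
        sv = place_positives(96, k, seed)
        outcome = run_sudoku(sv, weight=w)
        assert outcome.steps == 1
        assert outcome.ambiguous_retest_count == 0
        assert outcome.decoded_positives == sv.positives


class TestRunSudoku:
    def test_single_positive_costs(self):
        sv = place_positives(96, 1, seed=5)
        o = run_sudoku(sv, k_hat=1)
        assert (o.tests, o.steps) == (21, 1)
        assert o.pipettings == {1: 192, 8: 192, 16: 192}
        assert o.max_pool_size == 10

    def test_no_positives_no_retests(self):
        o = run_sudoku(SampleStatusVector.from_positives(96, []), k_hat=1)
        assert o.tests == 21 and o.ambiguous_retest_count == 0

    def test_overloaded_design_retests_candidates(self):
        sv = place_positives(96, 20, seed=5)
        o = run_sudoku(sv, weight=3)
        assert o.steps == 2
        assert o.tests == 34 + o.ambiguous_retest_count
        assert o.decoded_positives == sv.positives


class TestGridLayout:
    @pytest.mark.parametrize(
        "n,d,m,last", [(96, 10, 1, 96), (96, 5, 4, 21), (1536, 4, 96, 16)]
    )
    def test_grid_counts(self, n, d, m, last):
        layout = grid_layout(n, d)
        assert layout.m == m
        assert layout.occupancy[-1] == last
        assert sum(layout.occupancy) == n


class TestRunGrid2d:
    def test_four_5x5_grids_base_tests(self):
        o = run_grid2d(SampleStatusVector.from_positives(96, []), 5)
        assert o.tests == 40 and o.steps == 1

    def test_single_3x3_grid_ambiguous_diagonal(self):
        # positives on a diagonal: 2 positive rows x 2 positive columns
        sv = SampleStatusVector.from_positives(9, [0, 4])
        o = run_grid2d(sv, 3)
        assert o.ambiguous_retest_count == 4
        assert o.tests == 6 + 4
        assert o.steps == 2
        assert o.decoded_positives == {0, 4}

    def test_one_10x10_grid_single_positive(self):
        sv = place_positives(96, 1, seed=9)
        o = run_grid2d(sv, 10)
        assert (o.tests, o.steps) == (20, 1)
        assert o.pipettings == {1: 192, 8: 39, 16: 20}
        assert o.decoded_positives == sv.positives

    @given(st.integers(0, 500), st.integers(0, 6), st.sampled_from([3, 5, 10]))
    @settings(max_examples=80, derandomize=True)
    def test_always_decodes_truth(self, seed, k, d):
        sv = place_positives(96, k, seed)
        o = run_grid2d(sv, d)
        assert o.decoded_positives == sv.positives

    @given(st.integers(0, 300))
    @settings(max_examples=40, derandomize=True)
    def test_single_positive_line_decodes_without_retest(self, seed):
        """A grid with all positives in one row decodes unambiguously."""
        # put up to 3 positives in row 0 of a 5x5 grid
        import numpy as np

        rng = np.random.default_rng(seed)
        cols = rng.choice(5, size=rng.integers(1, 4), replace=False)
        sv = SampleStatusVector.from_positives(25, [int(c) for c in cols])
        o = run_grid2d(sv, 5)
        assert o.ambiguous_retest_count == 0
        assert o.decoded_positives == sv.positives


class TestBruteForceOracle:
    """Candidate sets agree with exhaustive enumeration of consistent truths."""

    def _consistent_union(self, n, pools, observed, max_k):
        union = set()
        found_sets = []
        for k in range(max_k + 1):
            for subset in itertools.combinations(range(n), k):
                chosen = set(subset)
                ok = all(
                    bool(chosen & set(p)) == res for p, res in zip(pools, observed)
                )
                if ok:
                    union |= chosen
                    found_sets.append(chosen)
        return union, found_sets

    @pytest.mark.parametrize("k", [0, 1, 2, 3])
    def test_sudoku_candidates_equal_consistency_union(self, k):
        n, windows = 12, tuple(select_windows(12, 2))
        design = SudokuDesign(n, windows)
        pools, keys = [], []
        for i, wi in enumerate(design.windows, start=1):
            for r in range(wi):
                members = [s for s in range(n) if s % wi == r]
                if members:
                    pools.append(members)
                    keys.append((i, r))
        for subset in itertools.combinations(range(n), k):
            truth = set(subset)
            observed = [bool(truth & set(p)) for p in pools]
            dec = sudoku_decode(dict(zip(keys, observed)), design)
            union, _ = self._consistent_union(n, pools, observed, max_k=k + 1)
            assert set(dec.candidates) == union
            assert truth <= set(dec.candidates)

    @pytest.mark.parametrize("k", [0, 1, 2, 3])
    def test_both_designs_decode_every_small_placement(self, k):
        n = 12
        for subset in itertools.combinations(range(n), k):
            sv = SampleStatusVector.from_positives(n, subset)
            assert run_sudoku(sv, weight=2).decoded_positives == set(subset)
            assert run_grid2d(sv, 3).decoded_positives == set(subset)
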