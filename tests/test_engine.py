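import numpy as np
import pytest

import fragmap as fm
from conftest import make_read, random_read, random_ref
from fragmap.engine import (
    HAVE_NUMBA,
    fragment_best,
    window_best_scores,
    window_series,
)
from fragmap.errors import ParameterError
from oracles import brute_best_ungapped, brute_maxss


class TestMaxScoringSubsequence:
    @pytest.mark.parametrize(
        "scores,expected",
        [
            ([5, 5, 5], (15.0, (0, 3))),
            ([5, -4, 5, 5, -4], (11.0, (0, 4))),
            ([-4, -4], (0.0, (0, 0))),
            ([], (0.0, (0, 0))),
        ],
    )
    def test_examples(self, scores, expected):
        assert fm.max_scoring_subsequence(scores) == expected

    def test_equals_quadratic_enumeration(self):
        # integer-valued scores so segment-sum ties are exact
        rng = np.random.default_rng(4)
        for _ in range(1000):
            n = int(rng.integers(0, 30))
            scores = rng.integers(-5, 6, size=n).astype(float)
            got = fm.max_scoring_subsequence(scores)
            want = brute_maxss(scores)
            assert got == want

    def test_float_scores_match_enumeration(self):
        rng = np.random.default_rng(5)
        for _ in range(200):
            scores = rng.normal(0, 3, size=int(rng.integers(1, 25)))
            got_score, got_bounds = fm.max_scoring_subsequence(scores)
            want_score, _ = brute_maxss(scores)
            assert got_score == pytest.approx(want_score, abs=1e-9)
            i, j = got_bounds
            assert got_score == pytest.approx(sum(scores[i:j]), abs=1e-9)


class TestScanFragment:
    def test_perfect_read_fragment0(self, toy_ref):
        hit = fm.scan_fragment(make_read("ACC"), toy_ref, 0)
        assert (hit.score, hit.window_offset) == (15.0, 0)
        assert hit.subseq_bounds == (0, 3)

    def test_junction_window_spans_fragments(self, toy_ref):
        # AGG sits at genome positions 5-7, crossing fragments 1 and 2
        hit = fm.scan_fragment(make_read("AGG"), toy_ref, 1)
        assert (hit.score, hit.window_offset) == (15.0, 5)

    def test_stride_two_scores_even_positions_only(self, toy_ref):
        hit = fm.scan_fragment(make_read("ACC"), toy_ref, 0, stride=2)
        assert (hit.score, hit.window_offset) == (10.0, 0)

    def test_stride_two_series_is_even_subsequence(self, toy_ref):
        rng = np.random.default_rng(6)
        for _ in range(50):
            read = random_read(rng, min_len=2, max_len=12)
            s = int(rng.integers(0, toy_ref.padded_length))
            s1 = window_series(read, toy_ref, s, stride=1)
            s2 = window_series(read, toy_ref, s, stride=2)
            np.testing.assert_array_equal(s2, s1[::2])


class TestScanAll:
    def test_global_best_fragment(self, toy_ref):
        hits = fm.scan_all(make_read("GGA"), toy_ref)
        best = max(hits, key=lambda h: h.score)
        assert (best.fragment_id, best.strand, best.score) == (2, "+", 15.0)

    def test_reverse_strand_symmetry(self, toy_ref):
        # revcomp of genome positions 3..9 ("GTAGGA")
        read = make_read(fm.reverse_complement("GTAGGA"))
        hits = fm.scan_all(read, toy_ref)
        best = max(hits, key=lambda h: h.score)
        assert best.strand == "-" and best.score == 30.0
        fwd_best = max(fm.scan_all(make_read("GTAGGA"), toy_ref), key=lambda h: h.score)
        assert fwd_best.score == best.score

    def test_all_n_read_scores_zero(self, toy_ref):
        hits = fm.scan_all(make_read("NNN", q=30), toy_ref)
        assert all(h.score == 0.0 for h in hits)

    def test_hit_order_and_counts(self, toy_ref):
        hits = fm.scan_all(make_read("ACC"), toy_ref)
        assert len(hits) == toy_ref.num_fragments * 2
        keys = [(h.fragment_id, h.strand) for h in hits]
        assert keys == [(f, s) for f in range(4) for s in "+-"]

    def test_stored_score_recomputable_from_bounds(self, toy_ref):
        rng = np.random.default_rng(7)
        for _ in range(30):
            read = random_read(rng, min_len=2, max_len=10)
            for hit in fm.scan_all(read, toy_ref):
                prof = read if hit.strand == "+" else read.reverse_complement()
                series = window_series(prof, toy_ref, hit.window_offset)
                i, j = hit.subseq_bounds
                assert hit.score == pytest.approx(float(series[i:j].sum()), abs=1e-9)

    def test_matches_scan_fragment(self, toy_ref):
        rng = np.random.default_rng(8)
        for _ in range(20):
            read = random_read(rng, min_len=2, max_len=10)
            hits = fm.scan_all(read, toy_ref)
            for hit in hits:
                single = fm.scan_fragment(read, toy_ref, hit.fragment_id, hit.strand)
                assert hit.score == pytest.approx(single.score, abs=1e-9)
                if hit.score > 0:
                    assert hit.window_offset == single.window_offset

    def test_equals_brute_force_ungapped_local(self):
        # phase-1 global best == exhaustive best ungapped local alignment
        rng = np.random.default_rng(9)
        for _ in range(150):
            ref = random_ref(rng)
            read = random_read(rng)
            hits = fm.scan_all(read, ref, with_bounds=False)
            got = max(h.score for h in hits)
            want = brute_best_ungapped(read, ref)
            assert got == pytest.approx(want, abs=1e-9)

    def test_planted_read_attains_maximum_possible_score(self):
        rng = np.random.default_rng(10)
        genome = "".join(rng.choice(list("ACGT"), size=600))
        ref = fm.ReferenceIndex("g", genome, 16)
        start = 123
        read = fm.ReadProfile("r", genome[start : start + 40], np.full(40, 40))
        hits = fm.scan_all(read, ref, with_bounds=False)
        best = max(hits, key=lambda h: h.score)
        max_possible = float(read.pssm.max(axis=1).sum())
        assert best.score == pytest.approx(max_possible, abs=1e-9)
        assert best.window_offset == start and best.strand == "+"


class TestKernelBackends:
    @pytest.mark.skipif(not HAVE_NUMBA, reason="numba backend absent")
    def test_numpy_fallback_matches_numba(self, toy_ref):
        rng = np.random.default_rng(11)
        for stride in (1, 2):
            read = random_read(rng, min_len=3, max_len=15)
            code = toy_ref.code_with_tail(len(read))
            a = window_best_scores(read.pssm, code, toy_ref.padded_length, stride, True)
            b = window_best_scores(read.pssm, code, toy_ref.padded_length, stride, False)
            np.testing.assert_allclose(a, b, atol=1e-9)

    def test_fragment_best_tie_breaks_to_smallest_offset(self):
        scores = np.array([1.0, 3.0, 3.0, 0.0, 5.0, 5.0])
        best, offs = fragment_best(scores, 3)
        np.testing.assert_array_equal(best, [3.0, 5.0])
        np.testing.assert_array_equal(offs, [1, 4])


class TestCapacity:
    @pytest.mark.parametrize("budget,expected", [(49152, 2432), (1920, 80), (65536, 3248)])
    def test_examples(self, budget, expected):
        assert fm.capacity_max_read_length(budget) == expected

    def test_result_is_tight(self):
        for budget in (49152, 1920, 65536, 12345):
            L = fm.capacity_max_read_length(budget)
            assert L % 16 == 0
            assert (L + 16) * 20 <= budget
            assert (L + 32) * 20 > budget

    def test_too_small_budget(self):
        with pytest.raises(ParameterError):
            fm.capacity_max_read_length(319)
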