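import math

import numpy as np
import pytest

import fragmap as fm
from fragmap.engine import FragmentHit
from fragmap.errors import FragmapError
from fragmap.select import decide_from_scans, default_mapq_threshold


def hit(frag, score, strand="+", ref="g", offset=None):
    return FragmentHit(ref, frag, strand, offset if offset is not None else frag * 10, score)


class TestMapqFromRatio:
    def test_repeat_threshold_value(self):
        assert round(fm.mapq_from_ratio(0.9), 1) == 15.2

    @pytest.mark.parametrize("ratio,expected", [(1.0, 0.0), (0.5, 100.0), (0.0, 254.0)])
    def test_closed_form(self, ratio, expected):
        assert fm.mapq_from_ratio(ratio) == pytest.approx(expected)

    def test_ratio_above_one_is_internal_error(self):
        with pytest.raises(FragmapError):
            fm.mapq_from_ratio(1.2)

    def test_strictly_decreasing_in_ratio(self):
        # below the 254 cap (ratio > 2^-2.54) the mapping is strictly monotone
        ratios = np.linspace(0.2, 1.0, 50)
        mapqs = [fm.mapq_from_ratio(r) for r in ratios]
        assert all(a > b for a, b in zip(mapqs, mapqs[1:]))


class TestDecide:
    def test_repeat_rejected(self):
        d = fm.decide([hit(0, 30.0), hit(5, 28.0), hit(9, 10.0)])
        assert d.best.fragment_id == 0 and d.second.fragment_id == 5
        assert d.ratio == pytest.approx(28 / 30)
        assert not d.accepted

    def test_clear_winner_accepted(self):
        d = fm.decide([hit(0, 30.0), hit(9, 10.0)])
        assert d.ratio == pytest.approx(1 / 3)
        assert d.mapq_real == pytest.approx(-100 * math.log2(1 / 3))
        assert d.accepted

    def test_adjacent_fragment_not_a_repeat(self):
        # junction overflow: fragments 0 and 1 can score the same placement
        d = fm.decide([hit(0, 30.0), hit(1, 29.0)])
        assert d.second is None and d.ratio == 0.0
        assert d.mapq_real == 254.0 and d.accepted

    def test_adjacent_on_other_strand_is_eligible(self):
        d = fm.decide([hit(0, 30.0), hit(1, 29.0, strand="-")])
        assert d.second is not None and not d.accepted

    def test_no_positive_score_rejected(self):
        d = fm.decide([hit(0, 0.0), hit(1, 0.0)])
        assert not d.accepted and d.mapq_real == 0.0

    def test_permutation_invariance(self):
        rng = np.random.default_rng(12)
        for _ in range(50):
            hits = [
                hit(int(f), float(s), strand="+" if rng.random() < 0.5 else "-")
                for f, s in zip(
                    rng.choice(50, size=8, replace=False), rng.integers(0, 40, size=8)
                )
            ]
            base = fm.decide(hits)
            for _ in range(5):
                perm = [hits[i] for i in rng.permutation(len(hits))]
                d = fm.decide(perm)
                assert (d.best, d.second, d.ratio, d.mapq_real, d.accepted) == (
                    base.best,
                    base.second,
                    base.ratio,
                    base.mapq_real,
                    base.accepted,
                )

    def test_threshold_flip_exactly_at_ratio_point_nine(self):
        thr = default_mapq_threshold(0.9)
        assert thr == pytest.approx(-100 * math.log2(0.9), abs=1e-12)
        for ratio in [0.9 - 1e-9, 0.9, 0.9 + 1e-9]:
            d = fm.decide([hit(0, 1.0), hit(7, ratio)])  # ratio is exact: x/1.0
            assert d.accepted == (ratio < 0.9)
            assert d.accepted == (d.mapq_real > thr)

    def test_raising_mapq_threshold_monotone_filter(self):
        rng = np.random.default_rng(13)
        hit_sets = []
        for _ in range(60):
            hit_sets.append(
                [hit(int(f), float(s)) for f, s in
                 zip(rng.choice(40, size=5, replace=False), rng.uniform(0, 30, size=5))]
            )
        prev = None
        for thr in [0.0, 15.2, 62.0, 150.0, 254.0]:
            n_acc = sum(
                fm.decide(hs, mapq_threshold=thr).accepted for hs in hit_sets
            )
            if prev is not None:
                assert n_acc <= prev
            prev = n_acc


class TestDecideFromScans:
    def _scans_from_hits(self, hits, nf=50):
        # rebuild the array form the pipeline produces
        scans = []
        for strand in "+-":
            scores = np.zeros(nf)
            offs = np.arange(nf) * 10
            for h in hits:
                if h.strand == strand:
                    scores[h.fragment_id] = h.score
                    offs[h.fragment_id] = h.window_offset
            scans.append(("g", strand, scores, offs))
        return scans

    def test_matches_object_path(self):
        rng = np.random.default_rng(14)
        nf = 50
        for _ in range(100):
            frags = rng.choice(nf, size=6, replace=False)
            hits = [
                hit(int(f), float(rng.integers(0, 40)),
                    strand="+" if rng.random() < 0.5 else "-")
                for f in frags
            ]
            # object path needs every (fragment, strand) represented
            full = {(h.fragment_id, h.strand): h for h in hits}
            all_hits = [
                full.get((f, s), hit(f, 0.0, strand=s))
                for f in range(nf)
                for s in "+-"
            ]
            want = fm.decide(all_hits)
            got = decide_from_scans(self._scans_from_hits(hits, nf))
            assert (got.accepted, got.ratio, got.mapq_real) == (
                want.accepted,
                want.ratio,
                want.mapq_real,
            )
            assert (got.best.fragment_id, got.best.strand) == (
                want.best.fragment_id,
                want.best.strand,
            )
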