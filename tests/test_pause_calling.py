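"""Pileup, scoring, calling, annotation and the start-codon density profile."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from rnetseq.io_formats import FeatureRecord, FootprintRead
from rnetseq.pause_calling import (EndCoverage, annotate_pauses, call_pauses,
                                   compute_pause_score, pause_density_profile,
                                   pileup_3prime_ends, score_track)


def cov_from_plus(counts):
    counts = np.asarray(counts)
    return EndCoverage("ref", counts, np.zeros_like(counts))


class TestPileup:
    def test_counts_by_end3(self):
        reads = [FootprintRead("ref", "+", 50, 18)] * 3
        cov = pileup_3prime_ends(reads, 100, "ref")
        assert cov.plus[50] == 3
        assert cov.total_mapped == 3

    def test_no_reads_gives_zero_arrays(self):
        cov = pileup_3prime_ends([], 10, "ref")
        assert cov.total_mapped == 0
        assert (cov.plus == 0).all() and (cov.minus == 0).all()

    def test_strands_kept_separate(self):
        reads = [FootprintRead("ref", "+", 5, 18), FootprintRead("ref", "-", 5, 18)]
        cov = pileup_3prime_ends(reads, 10, "ref")
        assert cov.plus[5] == 1 and cov.minus[5] == 1

    def test_out_of_bounds_read_rejected(self):
        with pytest.raises(ValueError):
            pileup_3prime_ends([FootprintRead("ref", "+", 10, 18)], 10, "ref")


class TestPauseScore:
    def test_uniform_coverage_scores_one(self):
        cov = cov_from_plus(np.full(501, 7))
        assert compute_pause_score(cov, 250, "+") == pytest.approx(1.0)

    def test_spike_over_flat_flank_oracle(self):
        # counts ...,2,2,2,40,2,2,2,... window_half=3: flank mean 2 -> score 20
        counts = np.array([2, 2, 2, 40, 2, 2, 2])
        cov = cov_from_plus(counts)
        assert compute_pause_score(cov, 3, "+", window_half=3) == pytest.approx(20.0)

    def test_zero_focal_count_scores_zero(self):
        counts = np.array([5, 0, 5])
        cov = cov_from_plus(counts)
        assert compute_pause_score(cov, 1, "+", window_half=1) == 0.0

    def test_zero_flank_capped(self):
        counts = np.array([0, 9, 0])
        cov = cov_from_plus(counts)
        assert compute_pause_score(cov, 1, "+", window_half=1) == 1e6

    def test_out_of_range_position(self):
        with pytest.raises(ValueError):
            compute_pause_score(cov_from_plus(np.ones(5, dtype=int)), 9, "+")

    @given(st.integers(min_value=1, max_value=50))
    @settings(max_examples=20, deadline=None, derandomize=True)
    def test_scale_invariance(self, k):
        rng = np.random.default_rng(0)
        counts = rng.poisson(3, size=400)
        s1 = score_track(counts, 50)
        s2 = score_track(counts * k, 50)
        np.testing.assert_allclose(s1, s2, rtol=1e-12)

    def test_track_matches_scalar_everywhere(self):
        rng = np.random.default_rng(1)
        counts = rng.poisson(2, size=300)
        cov = cov_from_plus(counts)
        track = score_track(counts, 40)
        for pos in [0, 1, 39, 150, 298, 299]:
            assert track[pos] == pytest.approx(
                compute_pause_score(cov, pos, "+", 40))


class TestCallPauses:
    def background(self):
        counts = np.full(1000, 2)
        return counts

    def test_isolated_spike_called(self):
        counts = self.background()
        counts[500] = 60
        pauses = call_pauses(cov_from_plus(counts), min_score=20, min_count=10)
        assert [(p.position, p.count) for p in pauses] == [(500, 60)]

    def test_cluster_keeps_max_count(self):
        counts = self.background()
        counts[500], counts[501] = 30, 40  # 1 nt apart: same cluster
        pauses = call_pauses(cov_from_plus(counts), min_score=5, min_count=10,
                             cluster_radius=2)
        assert [(p.position, p.count) for p in pauses] == [(501, 40)]

    def test_cluster_tie_breaks_to_smallest_coordinate(self):
        counts = self.background()
        counts[500], counts[501] = 40, 40
        pauses = call_pauses(cov_from_plus(counts), min_score=5, min_count=10)
        assert [p.position for p in pauses] == [500]

    def test_strong_flag_above_fifty(self):
        counts = self.background()
        counts[500] = 150  # score ~75
        [p] = call_pauses(cov_from_plus(counts))
        assert p.score > 50 and p.strong

    def test_score_just_below_strong_cut_not_flagged(self):
        counts = self.background()
        counts[500] = 80  # score ~40
        [p] = call_pauses(cov_from_plus(counts))
        assert not p.strong

    def test_raising_min_score_never_adds_pauses(self, small_coverage):
        cov = small_coverage["WT"]
        calls = {s: {(p.position, p.strand) for p in call_pauses(cov, min_score=s)}
                 for s in (10, 20, 40)}
        assert calls[40] <= calls[20] <= calls[10]

    def test_empty_result_allowed(self):
        pauses = call_pauses(cov_from_plus(np.ones(100, dtype=int)))
        assert pauses == []


class TestAnnotate:
    @pytest.fixture
    def features(self):
        return [FeatureRecord("orf1", "ref", 100, 400, "+", "ORF"),
                FeatureRecord("utr1", "ref", 50, 100, "+", "5UTR"),
                FeatureRecord("orf2", "ref", 600, 900, "-", "ORF")]

    def mkpause(self, pos, strand):
        from rnetseq.pause_calling import PauseSite
        return PauseSite("ref", pos, strand, 30, 25.0)

    def test_same_strand_orf(self, features):
        [p] = annotate_pauses([self.mkpause(200, "+")], features)
        assert p.context == "ORF" and p.gene_id == "orf1"

    def test_utr_context(self, features):
        [p] = annotate_pauses([self.mkpause(60, "+")], features)
        assert p.context == "5UTR"

    def test_antisense_when_only_opposite_strand_feature(self, features):
        [p] = annotate_pauses([self.mkpause(200, "-")], features)
        assert p.context == "antisense"

    def test_intergenic(self, features):
        [p] = annotate_pauses([self.mkpause(450, "+")], features)
        assert p.context == "intergenic"

    def test_dist_to_start_zero_at_the_A_of_ATG(self, features):
        [p] = annotate_pauses([self.mkpause(100, "+")], features)
        assert p.dist_to_start == 0
        [p] = annotate_pauses([self.mkpause(899, "-")], features)
        assert p.dist_to_start == 0

    def test_dist_to_start_sign_convention(self, features):
        # 10 nt into the ORF -> +10; upstream of the start -> negative
        [p] = annotate_pauses([self.mkpause(110, "+")], features)
        assert p.dist_to_start == 10
        [p] = annotate_pauses([self.mkpause(95, "+")], features)
        assert p.dist_to_start == -5
        [p] = annotate_pauses([self.mkpause(889, "-")], features)
        assert p.dist_to_start == 10


class TestDensityProfile:
    @pytest.fixture
    def features(self):
        return [FeatureRecord(f"g{i}", "ref", 1000 * i + 100, 1000 * i + 700, "+",
                              "ORF") for i in range(4)]

    def test_single_offset_spike(self, features):
        pauses = annotate_pauses(
            [TestAnnotate.mkpause(self, 1000 * i + 102, "+") for i in range(4)],
            features)
        prof = pause_density_profile(pauses, features, half_window=20)
        assert prof[20 + 2] == pytest.approx(1.0)  # 4 pauses / 4 genes at +2
        assert prof.sum() == pytest.approx(1.0)

    def test_empty_pause_list_gives_zero_profile(self, features):
        prof = pause_density_profile([], features)
        assert (prof == 0).all()

    def test_uniform_offsets_give_flat_profile(self, features):
        pauses = []
        for i in range(4):
            for off in range(0, 41, 4):
                pauses.append(TestAnnotate.mkpause(self, 1000 * i + 100 + off, "+"))
        prof = pause_density_profile(annotate_pauses(pauses, features), features,
                                     half_window=20)
        filled = prof[prof > 0]
        assert len(set(np.round(filled, 12))) == 1

    def test_no_orfs_is_an_error(self):
        with pytest.raises(ValueError):
            pause_density_profile([], [])


class TestRecoveryOnSyntheticData:
    def test_planted_pauses_recovered(self, small_sim, small_coverage):
        """Calls at default thresholds recover the well-supported planted
        pauses and call nothing outside the truth."""
        truth = small_sim["truth"]
        pauses = call_pauses(small_coverage["WT"])
        called = {(p.position, p.strand) for p in pauses}
        truth_keys = set(zip(truth["position"], truth["strand"]))
        assert called, "no pauses called"
        precision = len(called & truth_keys) / len(called)
        strong = truth[truth["weight_wt"] >= 30]
        strong_keys = set(zip(strong["position"], strong["strand"]))
        recall = len(called & strong_keys) / len(strong_keys)
        assert precision >= 0.95
        assert recall >= 0.95
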