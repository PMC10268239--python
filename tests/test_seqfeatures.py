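"""Pause-context windows, position matrices, consensus motif, hairpins."""

import numpy as np
import pytest

from rnetseq.io_formats import GenomeSequence, reverse_complement
from rnetseq.pause_calling import PauseSite
from rnetseq.seqfeatures import (HairpinCall, build_pfm, consensus_match,
                                 extract_windows, find_hairpins,
                                 hairpin_distance_profile, scramble)

# ---------------------------------------------------------------------------
# independent brute-force hairpin enumerator (oracle)

_WC = {("A", "T"), ("T", "A"), ("G", "C"), ("C", "G")}
_GU = {("G", "T"), ("T", "G")}


def _arm_pairs(arm5: str, arm3: str, allow_GU: bool) -> bool:
    ok = _WC | _GU if allow_GU else _WC
    return all((a, b) in ok for a, b in zip(arm5, arm3[::-1]))


def brute_hairpins(seq: str, stem_min=5, loop_range=(3, 8), allow_GU=True):
    """Enumerate every maximal perfect stem-loop by direct string slicing."""
    seq = seq.upper()
    n = len(seq)
    lo, hi = loop_range
    ok = _WC | _GU if allow_GU else _WC
    found = set()
    for i in range(n):
        for loop in range(lo, hi + 1):
            for s in range(stem_min, n):
                j = i + 2 * s + loop - 1
                if j >= n:
                    break
                if not _arm_pairs(seq[i:i + s], seq[i + s + loop:j + 1], allow_GU):
                    continue
                outward = (i > 0 and j + 1 < n
                           and (seq[i - 1], seq[j + 1]) in ok)
                inward = (loop - 2 >= lo
                          and (seq[i + s], seq[i + s + loop - 1]) in ok)
                if not outward and not inward:
                    found.add((i, s, loop, j, n - 1 - j))
    return found


def as_tuples(calls):
    return {(h.arm5_start, h.stem_length, h.loop_length, h.arm3_end, h.distance)
            for h in calls}


# ---------------------------------------------------------------------------

class TestExtractWindows:
    def test_plus_strand_indexing_oracle(self):
        # genome GGATCC, pause at index 3 ('T'): -2='A', -1='T', +1='C'
        g = GenomeSequence("g", "GGATCC")
        [w] = extract_windows(g, [PauseSite("g", 3, "+", 1, 1.0)],
                              upstream=2, downstream=1)
        assert (w.base(-2), w.base(-1), w.base(+1)) == ("A", "T", "C")

    def test_minus_strand_equals_revcomp_of_mirrored_plus(self):
        rng = np.random.default_rng(3)
        seq = "".join(rng.choice(list("ACGT"), size=60))
        g = GenomeSequence("g", seq)
        grc = GenomeSequence("g", reverse_complement(seq))
        pos = 30
        [w_minus] = extract_windows(g, [PauseSite("g", pos, "-", 1, 1.0)])
        [w_plus] = extract_windows(grc, [PauseSite("g", 59 - pos, "+", 1, 1.0)])
        assert w_minus.seq == w_plus.seq

    def test_window_off_reference_start_skipped(self):
        g = GenomeSequence("g", "ACGTACGTAC")
        assert extract_windows(g, [PauseSite("g", 2, "+", 1, 1.0)],
                               upstream=16) == []

    def test_offset_zero_does_not_exist(self):
        g = GenomeSequence("g", "GGATCC")
        [w] = extract_windows(g, [PauseSite("g", 3, "+", 1, 1.0)],
                              upstream=2, downstream=1)
        with pytest.raises(ValueError):
            w.base(0)
        assert 0 not in w.offsets


class TestPositionMatrix:
    def windows(self, seqs, upstream=2, downstream=1):
        from rnetseq.seqfeatures import PauseWindow
        return [PauseWindow("g", 0, "+", upstream, downstream, s) for s in seqs]

    def test_uniform_base_gives_two_bits(self):
        pfm = build_pfm(self.windows(["AAG", "CAG", "TAG", "GAG"]))
        assert pfm.information[-1] == pytest.approx(2.0)   # all G at -1...
        assert pfm.frequencies.loc[-1, "A"] == pytest.approx(1.0)

    def test_fifty_fifty_offset_has_one_bit(self):
        pfm = build_pfm(self.windows(["GAG", "GAC", "CAG", "CAC"]))
        assert pfm.information[-2] == pytest.approx(1.0)
        assert pfm.information[+1] == pytest.approx(1.0)

    def test_single_window_is_two_bits_everywhere(self):
        pfm = build_pfm(self.windows(["GAT"]))
        assert (np.abs(pfm.information.to_numpy() - 2.0) < 1e-12).all()

    def test_ic_bounds_and_frequency_sums(self):
        rng = np.random.default_rng(5)
        seqs = ["".join(rng.choice(list("ACGT"), size=3)) for _ in range(40)]
        pfm = build_pfm(self.windows(seqs))
        assert ((pfm.information >= 0) & (pfm.information <= 2)).all()
        np.testing.assert_allclose(pfm.frequencies.sum(axis=1), 1.0)

    def test_stratified_matrices(self):
        from rnetseq.seqfeatures import PauseWindow
        ws = [PauseWindow("g", i, "+", 2, 1, s)
              for i, s in enumerate(["GAG", "GAC", "CAT", "CAT"])]
        strata = build_pfm(ws, stratify_by={(0, "+"): "long", (1, "+"): "long",
                                            (2, "+"): "short", (3, "+"): "short"})
        assert set(strata) == {"long", "short"}
        assert strata["short"].frequencies.loc[-1, "A"] == 1.0


class TestConsensusMatch:
    def mkwin(self, mapping):
        from rnetseq.seqfeatures import PauseWindow
        bases = []
        for off in range(-16, 3):
            if off == 0:
                continue
            bases.append(mapping.get(off, "A"))
        return PauseWindow("g", 0, "+", 16, 2, "".join(bases))

    def test_full_match_scores_four(self):
        w = self.mkwin({-10: "G", -9: "G", -1: "C", 1: "G"})
        score, hits = consensus_match(w)
        assert score == 4 and all(hits.values())

    def test_all_A_scores_zero(self):
        score, _ = consensus_match(self.mkwin({}))
        assert score == 0  # A is a purine: no -1Y point

    def test_single_element_T_at_minus_one(self):
        score, hits = consensus_match(self.mkwin({-1: "T"}))
        assert score == 1 and hits[-1]

    def test_short_window_rejected(self):
        from rnetseq.seqfeatures import PauseWindow
        with pytest.raises(ValueError):
            consensus_match(PauseWindow("g", 0, "+", 4, 1, "ACGTA"))


class TestFindHairpins:
    def test_planted_stem_loop_matches_oracle(self):
        seq = "AAAAGGGGGTTTTCCCCC" + "A" * 12
        for gu in (True, False):
            calls = as_tuples(find_hairpins(seq, allow_GU=gu))
            assert calls == brute_hairpins(seq, allow_GU=gu)
        # without G.U wobble there is exactly the planted hairpin
        [h] = find_hairpins(seq, allow_GU=False)
        assert (h.stem_length, h.loop_length, h.distance) == (5, 4, 12)

    def test_poly_A_has_no_hairpins(self):
        assert find_hairpins("A" * 40) == []

    def test_hairpin_at_the_3_prime_end_has_distance_zero(self):
        seq = "GGGGGTTTTCCCCC"
        calls = find_hairpins(seq, allow_GU=False)
        assert any(h.distance == 0 for h in calls)
        assert as_tuples(calls) == brute_hairpins(seq, allow_GU=False)

    @pytest.mark.parametrize("allow_gu", [True, False])
    def test_agrees_with_brute_force_on_random_40mers(self, allow_gu):
        """Exhaustive scanner vs independent enumerator on 200 random 40-mers."""
        rng = np.random.default_rng(42)
        for _ in range(200):
            seq = "".join(rng.choice(list("ACGT"), size=40))
            assert as_tuples(find_hairpins(seq, allow_GU=allow_gu)) == \
                brute_hairpins(seq, allow_GU=allow_gu), seq

    def test_reverse_complement_symmetry(self):
        """A hairpin in a sequence maps to a hairpin in the reverse
        complement at mirrored coordinates (stems are self-symmetric)."""
        rng = np.random.default_rng(7)
        for _ in range(50):
            seq = "".join(rng.choice(list("ACGT"), size=40))
            fw = as_tuples(find_hairpins(seq, allow_GU=False))
            rc = as_tuples(find_hairpins(reverse_complement(seq), allow_GU=False))
            n = len(seq)
            mirrored = {(n - 1 - j, s, l, n - 1 - i, (n - 1) - (n - 1 - i))
                        for (i, s, l, j, _) in fw}
            assert rc == mirrored


class TestHairpinDistanceProfile:
    def planted_seqs(self, n, distance, rng):
        seqs = []
        while len(seqs) < n:
            stem = "".join(rng.choice(list("ACGT"), size=6, p=[0.1, 0.4, 0.4, 0.1]))
            rc = reverse_complement(stem)
            loop = "".join(rng.choice(list("AT"), size=4))
            tail = "".join(rng.choice(list("ACGT"), size=distance))
            head = "".join(rng.choice(list("ACGT"), size=30 - 16 - distance))
            seqs.append(head + stem + loop + rc + tail)
        return seqs

    def test_mode_at_planted_distance(self):
        rng = np.random.default_rng(8)
        seqs = self.planted_seqs(60, 12, rng)
        prof = hairpin_distance_profile(seqs, seed=1)
        assert prof["real_count"].idxmax() == 12
        assert prof.loc[12, "real_count"] > 3 * max(prof.loc[12, "scrambled_mean"], 1)

    def test_scramble_of_homopolymer_is_identity(self):
        rng = np.random.default_rng(0)
        assert scramble("AAAA", rng) == "AAAA"
        prof = hairpin_distance_profile(["A" * 30], seed=3)
        assert (prof["real_count"] == prof["scrambled_mean"]).all()

    def test_same_seed_identical_profiles(self):
        rng = np.random.default_rng(2)
        seqs = self.planted_seqs(10, 11, rng)
        p1 = hairpin_distance_profile(seqs, seed=5, scramble_n=2)
        p2 = hairpin_distance_profile(seqs, seed=5, scramble_n=2)
        assert p1.equals(p2)

    def test_scramble_n_must_be_positive(self):
        with pytest.raises(ValueError):
            hairpin_distance_profile(["ACGT"], scramble_n=0)
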