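"""PWM construction, scanning, EM discovery and enrichment statistics."""
import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import oracles
from ciliareg.motifs import (MotifHit, PWM, build_pwm, discover_motif_em,
                             motif_enrichment, positional_profile, scan_pwm)
from ciliareg.simulate import X_BOX_CONSENSUS, revcomp


def _random_seq(rng, n):
    return "".join("ACGT"[b] for b in rng.integers(0, 4, n))


class TestBuildPWM:
    def test_identical_sites_without_pseudocount_are_one_hot(self):
        pwm = build_pwm(["ACGT"] * 5, pseudocount=0.0)
        expected = np.eye(4)[[0, 1, 2, 3]].T
        assert np.allclose(pwm.probs, expected)

    def test_large_pseudocount_approaches_uniform(self):
        pwm = build_pwm(["ACGT"] * 5, pseudocount=1e9)
        assert np.allclose(pwm.probs, 0.25, atol=1e-6)

    def test_columns_sum_to_one(self):
        rng = np.random.default_rng(0)
        sites = [_random_seq(rng, 10) for _ in range(25)]
        pwm = build_pwm(sites, pseudocount=0.5)
        assert np.allclose(pwm.probs.sum(axis=0), 1.0)

    def test_mixed_length_sites_rejected(self):
        with pytest.raises(ValueError):
            build_pwm(["ACGT", "ACG"])


class TestScan:
    def test_one_hot_scores_four_log2_four_bits_at_match(self):
        pwm = build_pwm(["ACGT"] * 5, pseudocount=0.0)
        hits = scan_pwm("GGACGTGG", pwm, threshold=8.0)
        fwd = [h for h in hits if h.strand == "+"]
        assert len(fwd) == 1 and fwd[0].offset == 2
        assert np.isclose(fwd[0].score, 8.0)

    def test_uniform_pwm_scores_zero_everywhere(self):
        pwm = PWM(probs=np.full((4, 6), 0.25))
        hits = scan_pwm("ACGTACGTACGT", pwm, threshold=0.0)
        assert all(np.isclose(h.score, 0.0) for h in hits)

    def test_sequence_shorter_than_motif_yields_nothing(self):
        pwm = PWM(probs=np.full((4, 8), 0.25))
        assert scan_pwm("ACG", pwm) == []

    def test_palindromic_pwm_hits_coincide_on_both_strands(self):
        pwm = build_pwm([X_BOX_CONSENSUS] * 10, pseudocount=1.0)
        rng = np.random.default_rng(1)
        seq = _random_seq(rng, 40) + X_BOX_CONSENSUS + _random_seq(rng, 40)
        hits = scan_pwm(seq, pwm)
        fwd = {(h.offset, round(h.score, 9)) for h in hits if h.strand == "+"}
        rev = {(h.offset, round(h.score, 9)) for h in hits if h.strand == "-"}
        assert fwd and fwd == rev

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_brute_force_scoring(self, seed):
        rng = np.random.default_rng(seed)
        sites = [_random_seq(rng, 6) for _ in range(20)]
        pwm = build_pwm(sites, pseudocount=0.5,
                        background=[0.3, 0.2, 0.2, 0.3])
        seq = _random_seq(rng, 50)
        got = [(h.offset, h.strand, round(h.score, 9))
               for h in scan_pwm(seq, pwm, threshold=-1e9)]
        want = [(o, s, round(sc, 9)) for o, s, sc in
                oracles.scan_oracle(seq, pwm.probs.tolist(),
                                    pwm.background.tolist(), -1e9)]
        assert got == want

    def test_reverse_complement_input_mirrors_hits(self):
        rng = np.random.default_rng(2)
        sites = [_random_seq(rng, 8) for _ in range(15)]
        pwm = build_pwm(sites, pseudocount=0.5)
        seq = _random_seq(rng, 60)
        fwd_hits = scan_pwm(seq, pwm, threshold=-1e9)
        rc_hits = scan_pwm(revcomp(seq), pwm, threshold=-1e9)
        L = pwm.width
        mirrored = sorted((len(seq) - L - h.offset,
                           "+" if h.strand == "-" else "-",
                           round(h.score, 9)) for h in rc_hits)
        original = sorted((h.offset, h.strand, round(h.score, 9))
                          for h in fwd_hits)
        assert mirrored == original

    @settings(max_examples=30, derandomize=True)
    @given(seq=st.text(alphabet="ACGT", min_size=10, max_size=60))
    def test_score_multiset_invariant_under_reverse_complement(self, seq):
        pwm = build_pwm(["ACGTAC", "AAGTAC", "ACGTCC"], pseudocount=0.5)
        fwd = sorted(round(h.score, 9) for h in scan_pwm(seq, pwm, threshold=-1e9))
        rev = sorted(round(h.score, 9)
                     for h in scan_pwm(revcomp(seq), pwm, threshold=-1e9))
        assert fwd == rev

    def test_n_windows_are_skipped(self):
        pwm = build_pwm(["ACGT"] * 5, pseudocount=0.5)
        hits = scan_pwm("NNACGTNN", pwm, threshold=-100)
        assert {h.offset for h in hits} == {2}


class TestDiscovery:
    def test_recovers_short_planted_word(self):
        rng = np.random.default_rng(10)
        word = "TTGACGTC"
        seqs = []
        for _ in range(20):
            s = _random_seq(rng, 80)
            j = rng.integers(0, 80 - len(word))
            seqs.append(s[:j] + word + s[j + len(word):])
        res = discover_motif_em(seqs, width=len(word), n_restarts=3, seed=5)
        assert res.pwm.consensus in (word, revcomp(word))
        assert res.gamma > 0.8

    def test_null_sequences_stay_near_background(self):
        rng = np.random.default_rng(11)
        seqs = [_random_seq(rng, 100) for _ in range(20)]
        res = discover_motif_em(seqs, width=8, n_restarts=2, seed=5)
        bg = res.pwm.background
        bg_only = sum(np.log(bg)[[("ACGT".index(b)) for b in s]].sum()
                      for s in seqs)
        # a spurious motif in random sequence buys little likelihood
        assert res.log_likelihood - bg_only < 0.02 * abs(bg_only)

    def test_objective_non_decreasing(self):
        rng = np.random.default_rng(12)
        seqs = [_random_seq(rng, 60) for _ in range(12)]
        res = discover_motif_em(seqs, width=6, n_restarts=1, seed=0)
        diffs = np.diff(res.ll_trajectory)
        assert (diffs >= -1e-8).all()

    def test_too_few_or_too_short_sequences_rejected(self):
        with pytest.raises(ValueError, match="10 sequences"):
            discover_motif_em(["ACGTACGT"] * 5, width=4)
        with pytest.raises(ValueError, match="width"):
            discover_motif_em(["ACGT"] * 12, width=8)

    def test_inverted_repeat_score_of_palindrome_is_one(self):
        pwm = build_pwm([X_BOX_CONSENSUS] * 8, pseudocount=0.5)
        assert pwm.inverted_repeat_score() > 0.99


class TestEnrichment:
    def _pwm(self):
        return build_pwm(["ACGTAC"] * 5, pseudocount=0.0)

    def test_worked_hypergeometric_case(self):
        pwm = self._pwm()
        with_motif = "GGACGTACGG"
        without = "GGGGGGGGGG"
        seqs = {}
        fg = {f"f{i}" for i in range(5)}
        bg = {f"b{i}" for i in range(15)}
        for i, g in enumerate(sorted(fg)):
            seqs[g] = with_motif if i < 3 else without
        for i, g in enumerate(sorted(bg)):
            seqs[g] = with_motif if i < 1 else without
        res = motif_enrichment(fg, bg, seqs, pwm)
        assert res["fg_with"] == 3 and res["bg_with"] == 1
        assert np.isclose(res["p_enrichment"], 155 / 4845, atol=1e-12)
        assert np.isclose(res["p_enrichment"],
                          oracles.hypergeom_upper_tail(3, 20, 4, 5), atol=1e-12)

    def test_empty_foreground_rejected(self):
        with pytest.raises(ValueError, match="foreground"):
            motif_enrichment(set(), {"b"}, {"b": "ACGT"}, self._pwm())

    def test_overlapping_sets_rejected(self):
        with pytest.raises(ValueError, match="disjoint"):
            motif_enrichment({"x"}, {"x"}, {"x": "ACGT"}, self._pwm())


class TestPositionalProfile:
    def test_hit_centered_on_anchor_has_distance_zero(self):
        hits = [MotifHit("s1", 93, "+", 5.0)]  # center = 93 + 7 = 100
        prof = positional_profile(hits, {"s1": 100}, motif_width=14, bin_width=25)
        row = prof.loc[prof["count"] > 0].iloc[0]
        assert row["bin_start"] <= 0 < row["bin_end"]

    def test_planted_offsets_give_histogram_mode(self):
        hits = [MotifHit(f"s{i}", 0, "+", 5.0) for i in range(10)]
        anchors = {f"s{i}": 107 for i in range(10)}  # center-anchor = -100
        prof = positional_profile(hits, anchors, motif_width=14, bin_width=25)
        mode = prof.loc[prof["count"].idxmax()]
        assert mode["bin_start"] <= -100 < mode["bin_end"]
        assert mode["count"] == 10

    def test_empty_hits_empty_histogram(self):
        prof = positional_profile([], {}, motif_width=14)
        assert prof.empty
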