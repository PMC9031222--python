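"""Spacer-remnant scanning, conservation profiles, LCS, mosaic decomposition."""

import numpy as np
import pytest

from oracles import dp_longest_common_substring

from mitorearr import (
    decompose_spacer,
    hypothesis_report,
    longest_common_substring,
    majority_conservation,
    null_band,
    segment_identity_scan,
)
from mitorearr.isp import ISPError
from mitorearr.simulate import mutate, random_seq


class TestSegmentIdentityScan:
    def test_exact_occurrence_scores_100_at_right_segment(self, rng):
        gene = random_seq(rng, 300, 0.8)
        hits = segment_identity_scan(gene[100:160], gene)
        assert hits[0].identity == 100.0
        assert hits[0].segment_start == 101 and hits[0].segment_end == 160

    def test_identity_100_only_for_exact_occurrence(self, rng):
        gene = random_seq(rng, 300, 0.8)
        query = mutate(rng, gene[100:160], 0.05)
        hits = segment_identity_scan(query, gene)
        assert hits[0].identity < 100.0

    def test_planted_remnant_recovered_top_1(self, rng):
        # contiguous 60% of a gene copied into a spacer, then 10% point
        # mutations: the top hit must overlap the planted segment
        recovered = 0
        trials = 40
        for _ in range(trials):
            gene = random_seq(rng, 300, 0.8)
            start = int(rng.integers(0, 120))
            planted = mutate(rng, gene[start:start + 180], 0.10)
            hits = segment_identity_scan(planted, gene)
            top = hits[0]
            overlap = (min(top.segment_end, start + 180)
                       - max(top.segment_start, start + 1))
            if overlap > 90:
                recovered += 1
        assert recovered >= 0.95 * trials

    def test_at_rich_noise_near_ties_exceed_planted_signal_ties(self, rng):
        # on 80% A+T composition a random spacer matches many distinct
        # candidate segments at similar identity (the ambiguity signature),
        # while a true planted remnant has one clear best segment
        trials = 30
        noise_ties, planted_ties, band = 0, 0, []
        for _ in range(trials):
            gene = random_seq(rng, 900, 0.8)
            noise = random_seq(rng, 60, 0.8)
            hits = segment_identity_scan(noise, gene)
            band.append(hits[0].identity)
            noise_ties += sum(h.near_tie for h in hits) >= 2
            planted = mutate(rng, gene[400:460], 0.10)
            phits = segment_identity_scan(planted, gene)
            planted_ties += sum(h.near_tie for h in phits) >= 2
        assert noise_ties >= 0.3 * trials
        assert planted_ties <= 0.1 * trials
        assert noise_ties > planted_ties
        # the noise band sits in the 60-80% identity range
        assert 55 <= float(np.mean(band)) <= 85

    def test_short_query_rejected(self, rng):
        with pytest.raises(ISPError):
            segment_identity_scan("ACGTACGT", random_seq(rng, 100, 0.8))

    def test_null_band_sits_below_strong_planted_signal(self, rng):
        gene = random_seq(rng, 300, 0.8)
        query = mutate(rng, gene[50:110], 0.05)
        p95 = null_band(query, gene, n_shuffles=30, seed=1)
        assert segment_identity_scan(query, gene)[0].identity > p95


class TestMajorityConservation:
    def test_identical_rows_fully_conserved(self):
        assert majority_conservation(["ACGTT"] * 4).percent_conserved == 100.0

    def test_hand_counted_example(self):
        prof = majority_conservation(["ACGT", "ACGA", "ACTA", "TCGA"])
        # every column has a modal residue in 3 or 4 of 4 rows
        assert prof.conserved_flags == [True, True, True, True]
        assert prof.percent_conserved == 100.0

    def test_majority_rule_boundary_is_strict(self):
        # 2 of 4 non-gap rows is not "more than 50%"
        prof = majority_conservation(["AA", "AA", "TT", "TT"])
        assert prof.percent_conserved == 0.0

    def test_disjoint_rows_zero(self):
        assert majority_conservation(["AC", "GT"]).percent_conserved == 0.0

    def test_row_order_invariance(self, rng):
        rows = ["".join(rng.choice(list("ACGT-"), 30)) for _ in range(6)]
        base = majority_conservation(rows)
        perm = majority_conservation([rows[i] for i in rng.permutation(6)])
        assert base.conserved_flags == perm.conserved_flags

    def test_gap_dominated_column_never_conserved(self):
        prof = majority_conservation(["A---", "A--C", "AA-C", "A--C"])
        # column 3 is all gaps; column 2 has 1/4 non-gap rows
        assert prof.conserved_flags[2] is False
        assert prof.conserved_flags[1] is False
        assert prof.conserved_flags[0] is True

    def test_unequal_lengths_rejected(self):
        with pytest.raises(ISPError):
            majority_conservation(["ACG", "AC"])

    def test_single_row_rejected(self):
        with pytest.raises(ISPError):
            majority_conservation(["ACGT"])


class TestLongestCommonSubstring:
    def test_embedded_segment_recovered(self, rng):
        seg = "AGTAAGCTAACTCAAGCTATTGGGTTCATACCC"
        # mismatched boundary characters keep the flanks from extending
        # the shared segment by chance
        a = random_seq(rng, 79, 0.8) + "A" + seg + "A" + random_seq(rng, 89, 0.8)
        b = random_seq(rng, 119, 0.8) + "C" + seg + "C" + random_seq(rng, 49, 0.8)
        res = longest_common_substring(a, b)
        assert res.length == 33 and res.substring == seg
        assert "CAT" in res.substring
        assert a[res.positions_a[0]:res.positions_a[0] + 33] == seg

    def test_disjoint_residue_sets_give_empty(self):
        res = longest_common_substring("AAAA", "GGGG")
        assert res.length == 0 and res.substring == ""

    def test_all_occurrence_positions_reported(self):
        res = longest_common_substring("XXABCXXABCXX", "ABC")
        assert res.length == 3
        assert res.positions_a == (2, 7) and res.positions_b == (0,)

    def test_matches_dp_oracle_on_random_pairs(self, rng):
        for _ in range(100):
            la, lb = int(rng.integers(1, 200)), int(rng.integers(1, 200))
            a = random_seq(rng, la, 0.6)
            b = random_seq(rng, lb, 0.6)
            res = longest_common_substring(a, b)
            assert res.length == dp_longest_common_substring(a, b)
            if res.length:
                assert res.substring in a and res.substring in b

    def test_empty_input_rejected(self):
        with pytest.raises(ISPError):
            longest_common_substring("", "ACGT")


class TestDecomposeSpacer:
    def test_two_source_mosaic_recovered_in_order(self, rng):
        hits = 0
        for _ in range(10):
            g1 = random_seq(rng, 150, 0.8)
            g2 = random_seq(rng, 150, 0.8)
            spacer = (mutate(rng, g1[30:95], 0.08)
                      + mutate(rng, g2[40:105], 0.08))
            segs = decompose_spacer(spacer, [("g1", g1), ("g2", g2)])
            if [s.candidate_gene for s in segs] == ["g1", "g2"]:
                hits += 1
        assert hits >= 8

    def test_segments_do_not_overlap(self, rng):
        g1, g2 = random_seq(rng, 150, 0.8), random_seq(rng, 150, 0.8)
        spacer = g1[10:80] + g2[20:90]
        segs = decompose_spacer(spacer, [("g1", g1), ("g2", g2)])
        for prev, nxt in zip(segs, segs[1:]):
            assert prev.spacer_end <= nxt.spacer_start

    def test_noise_with_high_floor_yields_empty_tiling(self, rng):
        segs = decompose_spacer(random_seq(rng, 80, 0.8),
                                [("g", random_seq(rng, 200, 0.8))],
                                identity_floor=92)
        assert segs == []

    def test_no_candidates_rejected(self, rng):
        with pytest.raises(ISPError):
            decompose_spacer(random_seq(rng, 50, 0.8), [])


class TestHypothesisReport:
    def test_exact_origin_wins_with_identity_100(self, rng):
        gene = random_seq(rng, 200, 0.8)
        other = random_seq(rng, 200, 0.8)
        rep = hypothesis_report(gene[50:110], [("src", gene), ("alt", other)])
        best = rep.best
        assert best.candidate_gene == "src" and best.best_identity == 100.0
        assert best.n_near_ties == 1
        assert rep.verdict == "src"

    def test_trnm_like_origin_beats_long_gene_alternative(self, rng):
        gene = random_seq(rng, 70, 0.8)       # short true source
        nad2 = random_seq(rng, 1000, 0.8)     # long competing candidate
        spacer = mutate(rng, gene[-40:], 0.10)
        rep = hypothesis_report(spacer, [("M", gene), ("nad2", nad2)])
        assert rep.verdict == "M"
        by = {r.candidate_gene: r for r in rep.results}
        assert by["M"].best_identity > by["nad2"].best_identity

    def test_pure_noise_flagged_ambiguous_against_null(self, rng):
        spacer = random_seq(rng, 60, 0.8)
        rep = hypothesis_report(
            spacer,
            [("g1", random_seq(rng, 300, 0.8)),
             ("g2", random_seq(rng, 300, 0.8))],
            null_shuffles=40, seed=3)
        assert all(r.flag == "ambiguous" for r in rep.results)
        assert rep.verdict == "inconclusive"

    def test_fewer_than_two_hypotheses_rejected(self, rng):
        with pytest.raises(ISPError):
            hypothesis_report(random_seq(rng, 50, 0.8),
                              [("only", random_seq(rng, 100, 0.8))])
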