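"""Cloverleaf folding, anticodon typing, compensatory changes, parsimony."""

import dendropy
import numpy as np
import pytest

from oracles import exhaustive_parsimony_score

from mitorearr import (
    anticodon_type,
    compare_stem_pairs,
    fitch_map,
    fold_to_template,
    generate_trna_family,
    generate_trna_sequence,
    templates,
    wagner_map,
)
from mitorearr.trna import TRNAError


@pytest.fixture(scope="module")
def tpl():
    return templates()


S1_OVERRIDES = {
    "GCT": {("an", 5): ("A", "T"), ("tp", 1): ("A", "T")},
    "ACT": {("an", 5): ("G", "C"), ("tp", 1): ("A", "T")},
    "TCT": {("an", 5): ("G", "C"), ("tp", 1): ("T", "A")},
}


class TestFoldToTemplate:
    def test_template_generated_sequence_folds_cleanly(self, tpl, rng):
        for name in ("standard", "S1", "M"):
            seq = generate_trna_sequence(tpl[name], rng, 0.8)
            out = fold_to_template(seq, tpl[name])
            assert out.ok and out.violated == [] and out.fraction_valid == 1.0

    def test_random_70mers_nearly_always_fail(self, tpl, rng):
        fails = sum(
            not fold_to_template("".join(rng.choice(list("ACGT"), 70)),
                                 tpl["standard"]).ok
            for _ in range(1000))
        assert fails >= 990

    def test_single_sided_stem_mutation_reported_as_violated(self, tpl, rng):
        t = tpl["standard"]
        seq = list(generate_trna_sequence(t, rng, 0.8))
        p5, p3 = t.stem_pairs()["an"][2]  # third anticodon-stem pair
        seq[p5] = {"A": "C", "C": "A", "G": "T", "T": "G"}[seq[p5]]
        out = fold_to_template("".join(seq), t)
        assert ("an", 3) in out.violated

    def test_length_out_of_range_rejected(self, tpl):
        with pytest.raises(TRNAError):
            fold_to_template("ACGT" * 10, tpl["standard"])   # 40 nt
        with pytest.raises(TRNAError):
            fold_to_template("ACGT" * 25, tpl["standard"])   # 100 nt

    def test_acceptance_invariant_to_trailing_unpaired_tail(self, tpl, rng):
        t = tpl["standard"]
        seq = generate_trna_sequence(t, rng, 0.8)
        base = fold_to_template(seq, t)
        extended = fold_to_template(seq + "ACGTACGT", t)
        assert base.ok == extended.ok
        assert base.violated == extended.violated

    def test_deterministic_and_idempotent(self, tpl, rng):
        seq = generate_trna_sequence(tpl["S1"], rng, 0.8)
        a = fold_to_template(seq, tpl["S1"])
        b = fold_to_template(seq, tpl["S1"])
        assert a.ok == b.ok and a.violated == b.violated


class TestAnticodonType:
    def test_s1_family_types_recovered_from_generated_family(self, tpl):
        seqs, truth = generate_trna_family(
            tpl["S1"], ["GCT", "ACT", "TCT"], 5, 0.10, seed=7,
            stem_overrides=S1_OVERRIDES)
        assert len(seqs) == 15
        for seq, (_, row) in zip(seqs, truth.iterrows()):
            out = fold_to_template(seq, tpl["S1"])
            assert out.ok
            assert anticodon_type(out.structure).label == row["anticodon"]

    def test_trnm_template_anticodon_cat(self, tpl, rng):
        seq = generate_trna_sequence(tpl["M"], rng, 0.8, anticodon="CAT")
        out = fold_to_template(seq, tpl["M"])
        ac = anticodon_type(out.structure)
        assert ac.triplet == "CAT" and ac.label is None

    def test_non_agn_template_passes_raw_triplet(self, tpl, rng):
        seq = generate_trna_sequence(tpl["standard"], rng, 0.8, anticodon="GAA")
        out = fold_to_template(seq, tpl["standard"])
        assert anticodon_type(out.structure).triplet == "GAA"

    def test_ambiguous_anticodon_rejected(self, tpl, rng):
        t = tpl["standard"]
        seq = list(generate_trna_sequence(t, rng, 0.8))
        lo, _ = t.anticodon_span
        seq[lo] = "N"
        out = fold_to_template("".join(seq), t)
        with pytest.raises(TRNAError):
            anticodon_type(out.structure)


class TestCompareStemPairs:
    def _structs(self, tpl):
        seqs, truth = generate_trna_family(
            tpl["S1"], ["GCT", "ACT", "TCT"], 1, 0.0, seed=5,
            stem_overrides=S1_OVERRIDES)
        return {row["anticodon"]: fold_to_template(seq, tpl["S1"]).structure
                for seq, (_, row) in zip(seqs, truth.iterrows())}

    def test_an5_at_vs_gc_fully_compensatory(self, tpl):
        s = self._structs(tpl)
        changes = {(c.stem, c.index): c for c in
                   compare_stem_pairs(s["GCT"], s["ACT"])}
        an5 = changes[("an", 5)]
        assert an5.kind == "fully_compensatory"
        assert {an5.pair1, an5.pair2} == {("A", "T"), ("G", "C")}

    def test_tp1_at_vs_ta_fully_compensatory(self, tpl):
        s = self._structs(tpl)
        changes = {(c.stem, c.index): c for c in
                   compare_stem_pairs(s["ACT"], s["TCT"])}
        assert changes[("tp", 1)].kind == "fully_compensatory"

    def test_identical_structures_all_identical(self, tpl):
        s = self._structs(tpl)["GCT"]
        assert all(c.kind == "identical" for c in compare_stem_pairs(s, s))

    def test_classification_symmetric(self, tpl, rng):
        seqs, _ = generate_trna_family(tpl["S1"], ["GCT", "TCT"], 1, 0.15,
                                       seed=13, stem_overrides=S1_OVERRIDES)
        a = fold_to_template(seqs[0], tpl["S1"]).structure
        b = fold_to_template(seqs[1], tpl["S1"]).structure
        fwd = [c.kind for c in compare_stem_pairs(a, b)]
        rev = [c.kind for c in compare_stem_pairs(b, a)]
        assert fwd == rev

    def test_template_mismatch_rejected(self, tpl, rng):
        a = fold_to_template(generate_trna_sequence(tpl["S1"], rng, 0.8),
                             tpl["S1"]).structure
        b = fold_to_template(generate_trna_sequence(tpl["standard"], rng, 0.8),
                             tpl["standard"]).structure
        with pytest.raises(TRNAError):
            compare_stem_pairs(a, b)


def _tree(newick):
    return dendropy.Tree.get(data=newick, schema="newick")


class TestFitchMap:
    def test_uniform_tips_zero_changes(self):
        cmap = fitch_map(_tree("((A,B),(C,D));"),
                         {t: {"x"} for t in "ABCD"})
        assert cmap.min_changes == 0
        assert all(s == frozenset({"x"}) for s in cmap.ancestral_states.values())

    def test_textbook_four_tip_case(self):
        cmap = fitch_map(_tree("((A,B),(C,D));"),
                         {"A": {"x"}, "B": {"x"}, "C": {"y"}, "D": {"y"}})
        assert cmap.min_changes == 1

    def test_score_bounded_by_tips_minus_one(self, rng):
        states = ["x", "y", "z"]
        for _ in range(20):
            tips = {t: {states[rng.integers(0, 3)]} for t in "ABCDEFGH"}
            cmap = fitch_map(_tree("(((A,B),(C,D)),((E,F),(G,H)));"), tips)
            assert 0 <= cmap.min_changes <= 7

    def test_matches_exhaustive_enumeration_on_random_trees(self, rng):
        states = ["x", "y", "z"]
        taxa = list("ABCDEFGH")
        for _ in range(100):
            # random 8-tip topology by sequential attachment
            newick = self._random_topology(taxa, rng)
            tips = {t: states[rng.integers(0, 3)] for t in taxa}
            tree = _tree(newick)
            score = fitch_map(tree, {k: {v} for k, v in tips.items()}).min_changes
            oracle = exhaustive_parsimony_score(_tree(newick), tips, states)
            assert score == oracle

    @staticmethod
    def _random_topology(taxa, rng):
        groups = list(taxa)
        while len(groups) > 1:
            i, j = sorted(rng.choice(len(groups), 2, replace=False))
            merged = f"({groups[i]},{groups[j]})"
            groups = [g for k, g in enumerate(groups) if k not in (i, j)]
            groups.append(merged)
        return groups[0] + ";"

    def test_missing_tip_state_listed(self):
        with pytest.raises(TRNAError, match="D"):
            fitch_map(_tree("((A,B),(C,D));"),
                      {"A": {"x"}, "B": {"x"}, "C": {"y"}})


class TestWagnerMap:
    def test_single_duplication_costs_one(self):
        cmap = wagner_map(_tree("((A,B),(C,D));"),
                          {"A": 2, "B": 2, "C": 1, "D": 1})
        assert cmap.min_changes == 1

    def test_copy_number_two_step_change_costs_two(self):
        cmap = wagner_map(_tree("(A,B);"), {"A": 0, "B": 2})
        assert cmap.min_changes == 2

    def test_planted_duplication_and_loss_scenario_recovered(self):
        # duplication (1 -> 2) at the ancestor of the left clade, one loss
        # (2 -> 1) on tip B: total two steps, no homoplasy planted
        tree = _tree("(((A,B),(C,D)),(E,F));")
        tips = {"A": 2, "B": 1, "C": 2, "D": 2, "E": 1, "F": 1}
        cmap = wagner_map(tree, tips)
        assert cmap.min_changes == 2
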