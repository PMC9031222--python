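"""Event detection, TDRL reachability/distance and pathway inference."""

import pytest

from conftest import SMALL_NAMES, perm_order
from oracles import all_single_event_products, bfs_tdrl_distances, one_tdrl_products

from mitorearr import (
    GeneOrderError,
    RearrangementEvent,
    StrandMismatchError,
    apply_event,
    apply_pathway,
    detect_single_event,
    explain_duplication_pathway,
    infer_pathways,
    min_tdrl_steps,
    minimal_tdrl_event,
    tdrl_reachable,
)
from mitorearr.simulate import SimConfig, generate_mitogenome


def elems_of(order):
    return tuple(zip(order.rendered(), (s for _, s in order.elements)))


class TestDetectSingleEvent:
    def test_miqgo_to_imqgo_is_one_transposition_in_mi_pair(self, reg):
        ev = detect_single_event(reg["MIQGO"], reg["IMQGO"])
        assert ev.kind == "transposition"
        assert set(ev.moved_block) <= {"M", "I"}

    def test_pango_to_imqgo_single_transposition(self, reg):
        ev = detect_single_event(reg["PanGO"], reg["IMQGO"])
        assert ev is not None and ev.kind == "transposition"

    def test_identity_gives_none(self, reg):
        assert detect_single_event(reg["MIQGO"], reg["MIQGO"]) is None

    def test_bemgo_needs_more_than_one_event(self, reg):
        assert detect_single_event(reg["MIQGO"], reg["BemGO"]) is None

    def test_detected_event_replays(self, reg):
        for target in ("IMQGO", "S1NGO", "ES1GO"):
            ev = detect_single_event(reg["MIQGO"], reg[target])
            assert apply_event(reg["MIQGO"], ev).signature() == \
                reg[target].signature()

    def test_agrees_with_brute_force_products(self, rng):
        for _ in range(200):
            n = int(rng.integers(3, 9))
            names = SMALL_NAMES[:n]
            strands = [("+", "-")[int(b)] for b in rng.integers(0, 2, n)]
            a = perm_order(names, strands)
            bs = [("+", "-")[int(b)] for b in rng.integers(0, 2, n)]
            b = perm_order(list(rng.permutation(names)), bs)
            reachable = elems_of(b) in all_single_event_products(elems_of(a))
            ev = detect_single_event(a, b)
            if elems_of(a) == elems_of(b):
                assert ev is None
            elif reachable:
                assert ev is not None
                assert elems_of(apply_event(a, ev)) == elems_of(b)
            else:
                assert ev is None


class TestTdrlReachable:
    def test_pango_to_miqgo(self, reg):
        ok, part = tdrl_reachable(reg["PanGO"], reg["MIQGO"])
        assert ok and part is not None

    def test_miqgo_to_es1go_and_s1ngo(self, reg):
        assert tdrl_reachable(reg["MIQGO"], reg["ES1GO"])[0]
        assert tdrl_reachable(reg["MIQGO"], reg["S1NGO"])[0]

    def test_full_reversal_of_three_not_one_move(self):
        a = perm_order(["A", "C", "D"])
        b = perm_order(["D", "C", "A"])
        ok, part = tdrl_reachable(a, b)
        assert not ok and part is None

    def test_interleaved_two_increasing_subsequences_not_reachable(self):
        # ranks (3,1,4,2): splits into increasing subsequences {3,4},{1,2}
        # but is not a concatenation of two runs, hence not one TDRL away
        a = perm_order(["A", "C", "D", "E"])
        b = perm_order(["D", "A", "E", "C"])
        assert not tdrl_reachable(a, b)[0]
        assert elems_of(b) not in one_tdrl_products(elems_of(a))

    def test_strand_mismatch_names_gene(self, reg):
        with pytest.raises(StrandMismatchError, match="E"):
            tdrl_reachable(reg["MIQGO"], reg["BemGO"])

    def test_agrees_with_enumeration_and_witness_replays(self, rng):
        for _ in range(200):
            n = int(rng.integers(3, 8))
            names = SMALL_NAMES[:n]
            a = perm_order(names)
            b = perm_order(list(rng.permutation(names)))
            expected = elems_of(b) in one_tdrl_products(elems_of(a))
            ok, part = tdrl_reachable(a, b)
            assert ok == expected
            if ok:
                ev = RearrangementEvent("tdrl", tuple(a.rendered()), 0, 0,
                                        tdrl_window=(0, n),
                                        tdrl_partition=part)
                assert elems_of(apply_event(a, ev)) == elems_of(b)


class TestMinTdrlSteps:
    def test_identity_is_zero(self, reg):
        assert min_tdrl_steps(reg["MIQGO"], reg["MIQGO"]) == 0

    def test_any_adjacent_swap_is_one(self):
        names = SMALL_NAMES[:7]
        a = perm_order(names)
        for i in range(6):
            swapped = names.copy()
            swapped[i], swapped[i + 1] = swapped[i + 1], swapped[i]
            assert min_tdrl_steps(a, perm_order(swapped)) == 1

    def test_full_reversal_of_five_is_three(self):
        names = SMALL_NAMES[:5]
        assert min_tdrl_steps(perm_order(names),
                              perm_order(names[::-1])) == 3

    def test_agrees_with_bfs_shortest_path(self, rng):
        for n in (4, 5, 6):
            names = tuple(SMALL_NAMES[:n])
            a = perm_order(list(names))
            start = elems_of(a)
            dist = bfs_tdrl_distances(start, max_depth=3)
            for _ in range(40):
                targ = tuple(rng.permutation(n))
                b = perm_order([names[i] for i in targ])
                expected = dist.get(elems_of(b))
                got = min_tdrl_steps(a, b)
                if expected is not None:
                    assert got == expected
                else:
                    assert got > 3


class TestInferPathways:
    def test_pango_to_miqgo_one_tdrl(self, reg):
        res = infer_pathways(reg["PanGO"], reg["MIQGO"], max_events=1,
                             allowed_kinds=frozenset({"tdrl"}))
        assert res.found and all(p.length == 1 for p in res.pathways)
        assert all(e.kind == "tdrl" for p in res.pathways for e in p.events)

    def test_miqgo_to_imqgo_one_transposition(self, reg):
        res = infer_pathways(reg["MIQGO"], reg["IMQGO"], max_events=1,
                             allowed_kinds=frozenset({"transposition"}))
        assert res.found and res.pathways[0].length == 1

    def test_identity_pathway_has_length_zero(self, reg):
        res = infer_pathways(reg["MIQGO"], reg["MIQGO"])
        assert res.found and res.pathways[0].length == 0

    def test_bound_exceeded_is_result_not_exception(self, reg):
        res = infer_pathways(reg["MIQGO"], reg["BemGO"], max_events=1,
                             allowed_kinds=frozenset({"transposition"}))
        assert not res.found and res.pathways == []

    def test_max_events_guard(self, reg):
        with pytest.raises(GeneOrderError):
            infer_pathways(reg["MIQGO"], reg["IMQGO"], max_events=4)

    def test_every_pathway_replays(self, rng):
        names = SMALL_NAMES[:6]
        a = perm_order(names)
        for _ in range(20):
            b = perm_order(list(rng.permutation(names)))
            res = infer_pathways(a, b, max_events=2)
            for p in res.pathways:
                assert elems_of(apply_pathway(a, p)) == elems_of(b)

    def test_two_step_search_finds_double_swap(self):
        names = SMALL_NAMES[:6]
        b = names.copy()
        b[0], b[1] = b[1], b[0]
        b[4], b[5] = b[5], b[4]
        res = infer_pathways(perm_order(names), perm_order(b), max_events=2,
                             allowed_kinds=frozenset({"transposition"}))
        assert res.found and res.pathways[0].length == 2


class TestMinimalTdrlEvent:
    def test_pango_to_miqgo_window_covers_miq_block_only(self, reg):
        ev = minimal_tdrl_event(reg["PanGO"], reg["MIQGO"])
        assert ev.tdrl_window == (31, 34)
        assert set(ev.moved_block) == {"I", "Q", "M"}
        assert apply_event(reg["PanGO"], ev).signature() == \
            reg["MIQGO"].signature()

    def test_identity_gives_none(self, reg):
        assert minimal_tdrl_event(reg["MIQGO"], reg["MIQGO"]) is None

    def test_unreachable_raises(self):
        a = perm_order(["A", "C", "D"])
        with pytest.raises(GeneOrderError):
            minimal_tdrl_event(a, perm_order(["D", "C", "A"]))


class TestExplainDuplicationPathway:
    def test_2ffgo_duplication_then_inverse_transposition(self):
        rec = generate_mitogenome(SimConfig(seed=2, arrangement="2FFGO"))
        pw = explain_duplication_pathway(rec)
        assert [e.kind for e in pw.events] == ["duplication",
                                               "inverse_transposition"]

    def test_4qgo_tandem_duplication_with_partial_random_loss(self):
        rec = generate_mitogenome(SimConfig(seed=2, arrangement="4QGO"))
        kinds = [e.kind for e in explain_duplication_pathway(rec).events]
        assert "partial_random_loss" in kinds
        assert kinds.count("duplication") >= 3

    def test_duplicate_free_record_gives_empty_pathway(self):
        rec = generate_mitogenome(SimConfig(seed=2, arrangement="MIQGO"))
        assert explain_duplication_pathway(rec).events == []
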