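"""Signed circular orders, breakpoint distance, event search and parsimony."""

import numpy as np
import pytest

from mitocomp.errors import InputError, NotFoundWithinBound
from mitocomp.gene_order import (
    RearrangementEvent,
    SignedGeneOrder,
    apply_event,
    apply_events,
    bfs_min_events,
    breakpoint_distance,
    enumerate_events,
    extract_order,
    infer_events,
    parsimony_scenario,
    restrict_to_shared,
)
from mitocomp.genome_io import Contig, FeatureKind, GeneFeature, MitoGenome


def order(*labels):
    return SignedGeneOrder(tuple(labels))


class TestNormalization:
    def test_idempotent(self):
        o = order("g2", "-cox1", "g1").normalized()
        assert o.normalized() == o

    def test_rotation_invariance(self):
        a = order("cox1", "g1", "-g2", "g3").normalized()
        b = order("g3", "cox1", "g1", "-g2").normalized()
        assert a == b

    def test_whole_circle_flip_invariance(self):
        # reading the other strand reverses order and flips all signs
        labels = ("cox1", "g1", "-g2", "g3")
        flipped = tuple(
            l[1:] if l.startswith("-") else "-" + l for l in reversed(labels)
        )
        assert order(*labels).normalized() == order(*flipped).normalized()

    def test_missing_anchor_rejected(self):
        with pytest.raises(InputError):
            order("g1", "g2").normalized()


class TestApplyEvents:
    def test_empty_event_list_is_identity(self):
        o = order("cox1", "g1", "g2")
        assert apply_events(o, []) == o

    def test_reversal_by_hand_oracle(self):
        # reversal of block [2,4) in (1,2,3,4,5) -> (1,2,-4,-3,5)
        o = order("cox1", "g2", "g3", "g4", "g5")
        got = apply_events(o, [RearrangementEvent("reversal", 2, 4)])
        assert got.labels == ("cox1", "g2", "-g4", "-g3", "g5")

    @pytest.mark.parametrize("kind", ["transposition", "reverse_transposition"])
    def test_event_then_inverse_is_identity(self, kind):
        o = order("cox1", "a", "b", "c", "d", "e")
        ev = RearrangementEvent(kind, 1, 3, 3)
        back = apply_events(o, [ev, ev.inverse()])
        assert back == o

    def test_reversal_is_involution(self):
        o = order("cox1", "a", "b", "c")
        ev = RearrangementEvent("reversal", 1, 3)
        assert apply_events(o, [ev, ev]) == o

    def test_out_of_range_block_rejected(self):
        o = order("cox1", "a", "b")
        with pytest.raises(InputError):
            apply_event(o.labels, RearrangementEvent("reversal", 0, 2))


class TestBreakpointDistance:
    def test_identical_orders_zero(self):
        o = order("cox1", "a", "b", "c")
        assert breakpoint_distance(o, o) == 0

    @pytest.mark.parametrize("start,end", [(1, 2), (2, 4), (1, 5), (3, 6)])
    def test_single_internal_reversal_gives_two(self, start, end):
        o = order("cox1", "a", "b", "c", "d", "e", "f")
        o2 = apply_events(o, [RearrangementEvent("reversal", start, end)])
        assert breakpoint_distance(o, o2) == 2

    def test_symmetry_on_random_pairs(self):
        rng = np.random.default_rng(7)
        base = order(*(["cox1"] + [f"g{i}" for i in range(1, 8)]))
        events = enumerate_events(8)
        for _ in range(30):
            evs = [events[rng.integers(len(events))]
                   for _ in range(rng.integers(0, 4))]
            other = apply_events(base, evs)
            assert breakpoint_distance(base, other) == breakpoint_distance(other, base)

    def test_label_set_mismatch_rejected(self):
        with pytest.raises(InputError):
            breakpoint_distance(order("cox1", "a"), order("cox1", "b"))


class TestInferEvents:
    def test_identical_orders_empty_list(self):
        o = order("cox1", "a", "b", "c")
        assert infer_events(o, o) == []

    def test_planted_single_transposition_recovered_as_one_transposition(self):
        base = order(*(["cox1"] + [f"g{i}" for i in range(1, 10)]))
        target = apply_events(
            base, [RearrangementEvent("transposition", 2, 4, 6)]
        )
        got = infer_events(base, target, max_events=2)
        assert len(got) == 1
        assert got[0].kind == "transposition"

    def test_replay_exactness_on_returned_solutions(self):
        rng = np.random.default_rng(12)
        base = order(*(["cox1"] + [f"g{i}" for i in range(1, 8)]))
        events = enumerate_events(8)
        for _ in range(10):
            evs = [events[rng.integers(len(events))]
                   for _ in range(rng.integers(1, 3))]
            target = apply_events(base, evs).normalized()
            got = infer_events(base, target, max_events=2)
            assert apply_events(base.normalized(), got).labels == target.labels

    def test_not_found_within_bound_raised(self):
        base = order(*(["cox1"] + [f"g{i}" for i in range(1, 10)]))
        evs = [
            RearrangementEvent("reversal", 1, 4),
            RearrangementEvent("transposition", 5, 7, 2),
            RearrangementEvent("reverse_transposition", 3, 6, 1),
        ]
        target = apply_events(base, evs)
        if breakpoint_distance(base, target) > 3:  # genuinely > 1 event away
            with pytest.raises(NotFoundWithinBound):
                infer_events(base, target, max_events=1)


class TestBfsOracle:
    def test_distance_to_self_zero(self):
        o = order("cox1", "a", "b")
        assert bfs_min_events(o, o) == 0

    def test_single_reversal_is_one(self):
        o = order("cox1", "a", "b", "c", "d")
        o2 = apply_events(o, [RearrangementEvent("reversal", 2, 4)])
        assert bfs_min_events(o, o2) == 1

    def test_agreement_with_heuristic_on_small_sample(self):
        rng = np.random.default_rng(99)
        base = order(*(["cox1"] + [f"g{i}" for i in range(1, 8)]))
        events = enumerate_events(8)
        for _ in range(25):
            k = int(rng.integers(0, 3))
            evs = [events[rng.integers(len(events))] for _ in range(k)]
            target = apply_events(base, evs)
            exact = bfs_min_events(base, target, cap=3)
            assert exact >= 0
            assert len(infer_events(base, target, max_events=3)) == exact

    def test_large_instance_guard(self):
        big = order(*(["cox1"] + [f"g{i}" for i in range(1, 12)]))
        with pytest.raises(InputError):
            bfs_min_events(big, big)


class TestParsimonyScenario:
    def test_four_identical_leaves_zero_events(self):
        o = order(*(["cox1"] + [f"g{i}" for i in range(1, 8)]))
        scen = parsimony_scenario({t: o for t in "ABCD"})
        assert scen.total_events == 0

    def test_star_truth_one_event_per_leaf(self):
        ancestor = order(*(["cox1"] + [f"g{i}" for i in range(1, 8)]))
        leaf_events = {
            "A": RearrangementEvent("reversal", 1, 3),
            "B": RearrangementEvent("transposition", 4, 6, 1),
            "C": RearrangementEvent("reversal", 5, 7),
            "D": RearrangementEvent("reverse_transposition", 2, 4, 5),
        }
        leaves = {t: apply_events(ancestor, [ev]) for t, ev in leaf_events.items()}
        scen = parsimony_scenario(leaves, (("A", "B"), ("C", "D")), k=1)
        assert scen.total_events == 4
        assert scen.internal_orders["X"].normalized().labels == ancestor.labels
        assert scen.internal_orders["Y"].normalized().labels == ancestor.labels

    def test_total_at_least_max_pairwise_minimum(self):
        ancestor = order(*(["cox1"] + [f"g{i}" for i in range(1, 8)]))
        leaves = {
            "A": ancestor,
            "B": apply_events(ancestor, [RearrangementEvent("reversal", 1, 4)]),
            "C": apply_events(ancestor, [RearrangementEvent("transposition", 2, 3, 5)]),
            "D": ancestor,
        }
        scen = parsimony_scenario(leaves, (("A", "B"), ("C", "D")), k=2)
        pair_min = max(
            bfs_min_events(leaves[u], leaves[v], cap=3)
            for u in "ABCD" for v in "ABCD" if u < v
        )
        assert scen.total_events >= pair_min


class TestExtractOrder:
    def _genome(self):
        # cox1(+) g1(+) trnX(-) g2(-) around a 400 bp circle
        contig = Contig("c", "A" * 400, circular=True)
        feats = [
            GeneFeature("cox1", FeatureKind.CDS, "c", 10, 100, "+"),
            GeneFeature("g1", FeatureKind.CDS, "c", 120, 200, "+"),
            GeneFeature("trnX", FeatureKind.tRNA, "c", 210, 270, "-"),
            GeneFeature("g2", FeatureKind.CDS, "c", 280, 380, "-"),
        ]
        return MitoGenome("t", [contig], feats)

    def test_forward_genome_all_positive_signs(self):
        got = extract_order(self._genome())
        assert got.labels == ("cox1", "g1", "-trnX", "-g2")

    def test_rotation_of_circular_contig_is_invariant(self):
        g = self._genome()
        r = 205  # rotate inside a gene gap
        rotated = Contig("c", g.contigs[0].seq[r:] + g.contigs[0].seq[:r],
                         circular=True)
        feats = [
            GeneFeature(f.gene_name, f.kind, "c", (f.start - r) % 400,
                        (f.end - r - 1) % 400 + 1, f.strand, f.stop_status)
            for f in g.features
        ]
        g2 = MitoGenome("t", [rotated], feats)
        assert extract_order(g2).labels == extract_order(g).labels

    def test_include_trna_false_drops_exactly_trnas(self):
        got = extract_order(self._genome(), include_trna=False)
        assert got.labels == ("cox1", "g1", "-g2")

    def test_missing_anchor_rejected(self):
        g = self._genome()
        g.features = [f for f in g.features if f.gene_name != "cox1"]
        with pytest.raises(InputError):
            extract_order(MitoGenome("t", g.contigs, g.features))

    def test_restrict_to_shared_drops_private_genes(self):
        a = order("cox1", "a", "b", "c")
        b = order("cox1", "b", "c", "d")
        ra, rb, dropped = restrict_to_shared(a, b)
        assert ra.gene_set() == rb.gene_set() == {"cox1", "b", "c"}
        assert dropped == ["a", "d"]
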