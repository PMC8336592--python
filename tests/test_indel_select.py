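"""Windows, penalties, conservative greedy and window-constrained ILP."""

import numpy as np
import pytest

from vgselect.graph_model import (
    ReferenceAxis,
    VariantLocus,
    VariantRecord,
    build_variation_graph,
)
from vgselect.indel_select import (
    compute_penalties,
    compute_windows,
    greedy_indel,
    ilp_indel,
    locus_penalty,
    window_removed_penalties,
)
from vgselect.oracle import window_start_bfs
from vgselect.snp_select import greedy_snp

from conftest import random_mixed_instance, random_snp_instance, snp_graph


def _axis(n=64):
    return ReferenceAxis("A" * n)


class TestWindows:
    def test_no_deletions_reduces_to_alpha_window(self):
        g = snp_graph(_axis(), [12])
        w = compute_windows(g, alpha=4)
        assert w.window_start[0] == 9  # p - alpha + 1

    def test_clamped_at_zero(self):
        g = snp_graph(_axis(), [2])
        assert compute_windows(g, alpha=10).window_start[0] == 0

    def test_deletion_stretches_window_left(self):
        # deletion edge v_5 -> v_10; from v_4 the path 1 labeled edge to v_5,
        # epsilon to v_10, 2 labeled edges to v_12 uses 3 < 4 labeled edges
        g = build_variation_graph(
            _axis(20), [VariantRecord.dele(5, 5), VariantRecord.snp(12, "C")]
        )
        w = compute_windows(g, alpha=4)
        assert dict(zip(g.variant_coordinates.tolist(), w.window_start.tolist())) == {
            5: 2,
            12: 4,
        }

    def test_chained_deletions(self):
        # v_2 ->eps v_6 ->eps v_9, locus at 10: from v_2 a single labeled edge
        # v_9->v_10 suffices, from v_1 two labeled edges are needed (not < 2)
        g = build_variation_graph(
            _axis(20),
            [VariantRecord.dele(2, 4), VariantRecord.dele(6, 3), VariantRecord.snp(10, "C")],
        )
        w = compute_windows(g, alpha=2)
        assert w.window_start[-1] == 2
        assert window_start_bfs(g, 2, 10) == 2

    def test_agrees_with_bfs_oracle(self, rng):
        for _ in range(30):
            L = int(rng.integers(40, 200))
            alpha = int(rng.integers(2, 21))
            g = random_mixed_instance(
                rng, length=L, n_loci=int(rng.integers(2, 8)), max_del=12
            )
            w = compute_windows(g, alpha)
            for idx, c in enumerate(g.variant_coordinates):
                assert w.window_start[idx] == window_start_bfs(g, alpha, int(c))

    def test_window_never_right_of_locus(self, rng):
        g = random_mixed_instance(rng, length=80, n_loci=6, max_del=10)
        w = compute_windows(g, 9)
        assert np.all(w.window_start <= g.variant_coordinates)


class TestPenalty:
    @pytest.mark.parametrize(
        "variants,expected",
        [
            ([VariantRecord.snp(5, "C")], 1),  # one substitution
            ([VariantRecord.ins(5, "A" * 7), VariantRecord.dele(5, 50)], 57),
            ([VariantRecord.dele(5, 50)], 50),
            ([VariantRecord.ins(5, "ACG")], 3),
            ([VariantRecord.ins(5, "ACG"), VariantRecord.snp(5, "C")], 4),
            ([VariantRecord.snp(5, "C"), VariantRecord.snp(5, "G")], 1),
            ([VariantRecord.dele(5, 3), VariantRecord.snp(5, "C")], 3),
        ],
    )
    def test_penalty_bounds(self, variants, expected):
        locus = VariantLocus(5, tuple(variants))
        assert locus_penalty(locus) == expected

    def test_penalty_at_least_one(self, rng):
        g = random_mixed_instance(rng, n_loci=6)
        assert compute_penalties(g).penalty.min() >= 1


class TestGreedyIndel:
    def test_reduces_to_snp_greedy_without_indels(self, rng):
        for _ in range(15):
            g = random_snp_instance(rng, 60, int(rng.integers(3, 10)))
            alpha, delta = int(rng.integers(2, 9)), int(rng.integers(0, 4))
            assert (
                greedy_indel(g, alpha=alpha, delta=delta).removed_coordinates
                == greedy_snp(g, alpha, delta).removed_coordinates
            )

    def test_single_sv_retained_under_short_read_budget(self):
        axis = ReferenceAxis("A" * 400)
        g = build_variation_graph(axis, [VariantRecord.dele(100, 50)])
        res = greedy_indel(g, alpha=150, delta=8)
        assert res.retained_coordinates == {100}  # penalty 50 > 8

    def test_budget_splits_shared_window(self):
        # three insertion loci of penalty 3 inside one shared window, delta=7:
        # 3+3 <= 7 but 3+3+3 > 7, so the third is retained
        axis = ReferenceAxis("A" * 40)
        g = build_variation_graph(
            axis,
            [VariantRecord.ins(10, "CCC"), VariantRecord.ins(11, "GGG"), VariantRecord.ins(12, "TTT")],
        )
        res = greedy_indel(g, alpha=10, delta=7)
        assert res.removed_coordinates == {10, 11}

    def test_outputs_satisfy_all_window_constraints(self, rng):
        for _ in range(20):
            g = random_mixed_instance(rng, n_loci=int(rng.integers(3, 8)))
            alpha, delta = int(rng.integers(3, 10)), int(rng.integers(0, 6))
            res = greedy_indel(g, alpha=alpha, delta=delta)
            windows = compute_windows(g, alpha)
            pens = compute_penalties(g)
            sums = window_removed_penalties(g, windows, pens, res.removed_coordinates)
            assert sums.max(initial=0) <= delta


class TestIlpIndel:
    def _three_locus_instance(self):
        # penalties {6, 4, 3}, variant counts {1, 1, 5}, one shared window
        axis = ReferenceAxis("A" * 40)
        recs = [VariantRecord.ins(5, "C" * 6), VariantRecord.ins(6, "G" * 4)]
        for allele in ("TTT", "TT", "CC", "G", "T"):
            recs.append(VariantRecord.ins(7, allele))
        return build_variation_graph(axis, recs)

    def test_outgains_greedy_on_weighted_instance(self):
        g = self._three_locus_instance()
        greedy = greedy_indel(g, alpha=20, delta=7)
        ilp = ilp_indel(g, alpha=20, delta=7, objective="variants")
        assert greedy.removed_coordinates == {5}  # left-first, gain 1
        assert ilp.removed_coordinates == {6, 7}  # gain 6 fits: 4 + 3 <= 7
        assert ilp.meta["objective"] == 6

    def test_zero_budget_removes_nothing(self):
        g = self._three_locus_instance()
        res = ilp_indel(g, alpha=20, delta=0, objective="positions")
        assert res.removed_coordinates == set()

    @pytest.mark.parametrize("objective", ["variants", "positions"])
    def test_dominates_greedy(self, rng, objective):
        for _ in range(25):
            g = random_mixed_instance(rng, n_loci=int(rng.integers(3, 8)))
            alpha, delta = int(rng.integers(3, 10)), int(rng.integers(0, 7))
            greedy = greedy_indel(g, alpha=alpha, delta=delta)
            ilp = ilp_indel(g, alpha=alpha, delta=delta, objective=objective)
            if objective == "positions":
                assert ilp.removed_locus_count >= greedy.removed_locus_count
            else:
                g_gain = g.total_variants - greedy.retained_variant_count
                i_gain = g.total_variants - ilp.retained_variant_count
                assert i_gain >= g_gain

    def test_outputs_satisfy_all_window_constraints(self, rng):
        for _ in range(15):
            g = random_mixed_instance(rng, n_loci=int(rng.integers(3, 8)))
            alpha, delta = int(rng.integers(3, 10)), int(rng.integers(0, 7))
            res = ilp_indel(g, alpha=alpha, delta=delta, objective="variants")
            windows = compute_windows(g, alpha)
            pens = compute_penalties(g)
            sums = window_removed_penalties(g, windows, pens, res.removed_coordinates)
            assert sums.max(initial=0) <= delta

    def test_snp_only_positions_matches_snp_constraints(self, rng):
        # without indels the window system coincides with the SNP one, so the
        # positions objective equals the optimal removed-locus count
        for _ in range(10):
            g = random_snp_instance(rng, 60, int(rng.integers(3, 9)))
            alpha, delta = int(rng.integers(2, 8)), int(rng.integers(0, 3))
            res = ilp_indel(g, alpha=alpha, delta=delta, objective="positions")
            assert res.removed_locus_count == greedy_snp(g, alpha, delta).removed_locus_count
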