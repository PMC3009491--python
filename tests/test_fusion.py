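import math

import numpy as np
import pytest

from generank import (
    RankList,
    assign_ratings,
    auc_based_weights,
    discounted_rating,
    drs_combine,
    ndos_combine,
    ndos_q,
    wdrs_combine,
)


def rank_list(label, order):
    return RankList(label, {g: r for r, g in enumerate(order, start=1)})


def mc_dominance_q(ratios, draws):
    """Monte-Carlo oracle: P(sorted uniforms componentwise <= sorted ratios)."""
    hit = np.all(draws <= np.sort(np.asarray(ratios)), axis=1)
    return hit.mean(), hit.std(ddof=1) / math.sqrt(len(hit))


class TestRatings:
    @pytest.mark.parametrize("rank,expected", [(4, 5), (2, 5), (13, 5), (3, 5),
                                               (21, 4), (100, 1), (1, 5), (20, 5)])
    def test_five_equal_bins_over_100(self, rank, expected):
        rl = RankList("s", {f"g{i}": i for i in range(1, 101)})
        assert assign_ratings(rl, 5)[f"g{rank}"] == expected

    def test_equal_halves(self):
        rl = RankList("s", {f"g{i}": i for i in range(1, 11)})
        ratings = assign_ratings(rl, 2)
        assert ratings["g5"] == 2 and ratings["g6"] == 1

    def test_more_levels_than_genes_rejected(self):
        rl = RankList("s", {"a": 1, "b": 2})
        with pytest.raises(ValueError, match="more rating levels"):
            assign_ratings(rl, 3)


class TestDiscountedRating:
    @pytest.mark.parametrize("rank,expected", [(4, 2.15), (2, 3.15), (13, 1.31)])
    def test_worked_example_two_decimals(self, rank, expected):
        assert round(discounted_rating(5, rank), 2) == expected

    def test_rank_three_exact(self):
        assert discounted_rating(5, 3) == pytest.approx(2.5)

    def test_no_discount_at_rank_one(self):
        assert discounted_rating(5, 1) == 5.0

    def test_strictly_decreasing_in_rank(self):
        rl = RankList("s", {f"g{i}": i for i in range(1, 101)})
        ratings = assign_ratings(rl, 5)
        dr = [discounted_rating(ratings[f"g{r}"], r) for r in range(1, 101)]
        assert all(a > b for a, b in zip(dr, dr[1:]))


class TestDrsCombine:
    def test_worked_example_combined_score(self, worked_example_lists):
        lists, target = worked_example_lists
        result = drs_combine(lists, levels=5)
        assert round(result.scores[target], 2) == 2.28
        assert result.n_sources[target] == 4

    def test_single_source_preserves_order(self):
        rl = rank_list("s", ["a", "b", "c", "d", "e", "f"])
        result = drs_combine([rl], levels=3)
        assert result.ranks == rl.ranks

    def test_adjusted_n_means_over_covering_sources(self):
        # gene "x" in 2 of 3 sources: score is the mean over those two
        l1 = rank_list("s1", ["x", "a", "b", "c"])
        l2 = rank_list("s2", ["a", "x", "b", "c"])
        l3 = rank_list("s3", ["a", "b", "c"])
        result = drs_combine([l1, l2, l3], levels=2)
        dr1 = discounted_rating(2, 1)
        dr2 = discounted_rating(2, 2)
        assert result.scores["x"] == pytest.approx((dr1 + dr2) / 2)
        assert result.n_sources["x"] == 2

    def test_source_order_invariance(self, worked_example_lists):
        lists, _ = worked_example_lists
        a = drs_combine(lists, levels=5)
        b = drs_combine(list(reversed(lists)), levels=5)
        assert a.scores == b.scores and a.ranks == b.ranks

    def test_linear_operation_count(self):
        genes = [f"g{i:02d}" for i in range(10)]
        for n in (2, 4, 8):
            lists = [rank_list(f"s{j}", genes) for j in range(n)]
            assert drs_combine(lists, levels=2).n_ops == n * len(genes)


class TestAucWeights:
    def test_floor_filters_then_normalizes(self):
        assert auc_based_weights({"A": 0.9, "B": 0.6}, floor=0.7) == {
            "A": 1.0, "B": 0.0,
        }

    def test_equal_aucs_give_equal_weights(self):
        w = auc_based_weights({c: 0.8 for c in "ABCD"}, floor=0.7)
        assert all(v == pytest.approx(0.25) for v in w.values())

    def test_proportional_to_auc_above_floor(self):
        aucs = {"PPI": 0.939, "BP": 0.942, "CC": 0.711, "MF": 0.869}
        w = auc_based_weights(aucs, floor=0.7)
        total = sum(aucs.values())
        for s in aucs:
            assert w[s] == pytest.approx(aucs[s] / total)
        assert sum(w.values()) == pytest.approx(1.0)

    def test_all_filtered_rejected(self):
        with pytest.raises(ValueError, match="no source passes"):
            auc_based_weights({"A": 0.5, "B": 0.69}, floor=0.7)


class TestWdrsCombine:
    def test_uniform_weights_match_drs(self, worked_example_lists):
        lists, _ = worked_example_lists
        weights = {rl.source_label: 0.25 for rl in lists}
        assert wdrs_combine(lists, weights, levels=5).ranks == \
            drs_combine(lists, levels=5).ranks

    def test_single_positive_weight_follows_that_source(self):
        l1 = rank_list("s1", ["a", "b", "c", "d"])
        l2 = rank_list("s2", ["d", "c", "b", "a"])
        result = wdrs_combine([l1, l2], {"s1": 1.0, "s2": 0.0}, levels=2)
        assert result.ranks == l1.ranks

    def test_weighted_sum_hand_computed(self):
        # full coverage: per-gene renormalization is a no-op and the score
        # is the plain weighted sum of discounted ratings
        l1 = rank_list("s1", ["x", "y", "z", "w"])
        l2 = rank_list("s2", ["y", "z", "w", "x"])
        weights = {"s1": 0.9, "s2": 0.1}
        result = wdrs_combine([l1, l2], weights, levels=2)

        def dr(rl, g):
            return discounted_rating(assign_ratings(rl, 2)[g], rl.ranks[g])
        for g in ("x", "y", "z", "w"):
            expected = 0.9 * dr(l1, g) + 0.1 * dr(l2, g)
            assert result.scores[g] == pytest.approx(expected)

    def test_zero_weight_only_gene_ranks_last(self):
        l1 = rank_list("s1", ["a", "b"])
        l2 = rank_list("s2", ["a", "b", "x"])
        result = wdrs_combine([l1, l2], {"s1": 1.0, "s2": 0.0}, levels=2)
        assert result.scores["x"] == 0.0
        assert result.ranks["x"] == 3


class TestNdosQ:
    def test_single_source_is_the_ratio(self):
        assert ndos_q([30], [100]) == pytest.approx(0.3)

    def test_two_source_closed_form(self):
        # Q = 2 r1 r2 - r1^2 for sorted ratios (r1, r2)
        assert ndos_q([10, 20], [100, 100]) == pytest.approx(
            2 * 0.1 * 0.2 - 0.1**2
        )
        assert ndos_q([20, 10], [100, 100]) == pytest.approx(0.03)

    def test_certain_event(self):
        assert ndos_q([100, 50, 7], [100, 50, 7]) == pytest.approx(1.0)

    def test_rank_exceeding_list_size_rejected(self):
        with pytest.raises(ValueError, match="exceeds"):
            ndos_q([5], [4])

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            ndos_q([], [])

    @pytest.mark.parametrize("n", [2, 3, 4])
    def test_matches_monte_carlo_dominance_oracle(self, n, rng):
        draws = np.sort(rng.random((200_000, n)), axis=1)
        for _ in range(20):
            ratios = np.round(rng.uniform(0.05, 1.0, size=n), 3)
            ranks = (ratios * 1000).astype(int)
            q = ndos_q(list(ranks), [1000] * n)
            est, se = mc_dominance_q(ratios, draws)
            assert abs(q - est) <= max(3 * se, 1e-4)


class TestNdosCombine:
    def test_single_source_preserves_order(self):
        rl = rank_list("s", ["a", "b", "c", "d"])
        assert ndos_combine([rl]).ranks == rl.ranks

    def test_unanimous_top_beats_unanimous_bottom(self):
        genes = [f"g{i}" for i in range(6)]
        lists = [rank_list(f"s{j}", genes) for j in range(3)]
        result = ndos_combine(lists)
        assert result.scores["g0"] < result.scores["g5"]
        assert result.ranks["g0"] == 1

    def test_quadratic_operation_count(self):
        genes = [f"g{i:02d}" for i in range(10)]
        counts = {}
        for n in (2, 4, 8):
            lists = [rank_list(f"s{j}", genes) for j in range(n)]
            counts[n] = ndos_combine(lists).n_ops
        # per gene the recursion does n(n+1)/2 inner steps
        assert counts[2] == 10 * 3
        assert counts[4] == 10 * 10
        assert counts[8] == 10 * 36

    def test_agreement_with_simulation_oracle(self, rng):
        """Random 3-source, 10-gene instances vs the dominance oracle."""
        genes = [f"g{i}" for i in range(10)]
        draws = np.sort(rng.random((200_000, 3)), axis=1)
        for _ in range(5):
            lists = [
                rank_list(f"s{j}", list(rng.permutation(genes))) for j in range(3)
            ]
            result = ndos_combine(lists)
            for g in genes[:3]:
                ratios = [rl.ranks[g] / rl.m for rl in lists]
                est, se = mc_dominance_q(ratios, draws)
                assert abs(result.scores[g] - est) <= 3 * se + 1e-4
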