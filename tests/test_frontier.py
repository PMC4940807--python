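"""Unit tests for the penalty-matrix frontier machinery."""

import numpy as np
import pytest

from paretoselect import (CriteriaTable, ParetoFrontierFinder,
                          accumulate_alpha, assess_gamma, beta_sums,
                          brute_force_frontier, build_delta, dominance_work,
                          pareto_frontier, peel_frontiers, tournament_frontier)
from conftest import random_table

W = 1000


class TestBuildDelta:
    def test_worked_example_first_criterion(self, worked):
        delta = build_delta(worked, 0, W)
        # {m^1} = 1, 3, 5, 7, 3, 4
        assert delta[0, 1] == -1      # 1 < 3: g1 beats g2
        assert delta[1, 4] == 0       # 3 = 3: tie g2/g5
        assert delta[3, 0] == W       # 7 > 1: g4 penalized vs g1
        assert (np.diag(delta) == 0).all()

    def test_pair_antisymmetry_exhaustive(self):
        rng = np.random.default_rng(11)
        table = random_table(rng, 200, 3)
        delta = build_delta(table, 1, W)
        pairs = {(int(delta[i, j]), int(delta[j, i]))
                 for i in range(200) for j in range(i + 1, 200)}
        assert pairs <= {(-1, W), (W, -1), (0, 0)}

    def test_index_out_of_range(self, worked):
        with pytest.raises(IndexError):
            build_delta(worked, 2, W)

    def test_penalty_must_exceed_criteria_count(self, worked):
        with pytest.raises(ValueError, match="penalty"):
            build_delta(worked, 0, W=2)

    def test_nonfinite_values_rejected(self):
        with pytest.raises(ValueError, match="finite"):
            CriteriaTable(["a", "b"], [[1.0, np.nan], [0.0, 1.0]], ["c1", "c2"])


class TestAlphaGamma:
    @pytest.mark.parametrize("d1, d2, expected", [
        (-1, -1, -2),    # better on both criteria
        (W, W, 2 * W),   # worse on both criteria
        (0, 0, 0),       # full tie
        (-1, W, W - 1),  # mixed: better on one, worse on the other
    ])
    def test_alpha_two_criteria_outcomes(self, d1, d2, expected):
        a = accumulate_alpha([np.array([[0, d1], [0, 0]]),
                              np.array([[0, d2], [0, 0]])])
        assert a[0, 1] == expected

    def test_alpha_attainable_values_c2(self):
        rng = np.random.default_rng(3)
        table = random_table(rng, 50, 2)
        alpha = accumulate_alpha([build_delta(table, k, W) for k in range(2)])
        assert set(np.unique(alpha)) <= {0, -1, W, -2, W - 1, 2 * W}

    def test_alpha_shape_mismatch(self):
        with pytest.raises(ValueError, match="shape"):
            accumulate_alpha([np.zeros((2, 2)), np.zeros((3, 3))])

    @pytest.mark.parametrize("alpha, C, expected", [
        (0, 2, W), (W, 2, W), (2 * W, 2, 2 * W),   # printed two-criteria rule
        (W - 1, 2, 0),                             # mixed outcome maps to 0
        (3 * W, 4, 2 * W), (4 * W, 4, 4 * W), (2998, 4, 0),
    ])
    def test_gamma_assessment(self, alpha, C, expected):
        gamma = assess_gamma(np.array([[alpha]]), C=C, W=W)
        assert gamma[0, 0] == expected

    def test_gamma_rejects_unproducible_alpha(self):
        # 500 = W - 500 would need 500 losses in a 2-criteria problem
        with pytest.raises(ValueError, match="not producible"):
            assess_gamma(np.array([[500]]), C=2, W=W)

    def test_gamma_exact_for_odd_criteria_count(self):
        # (C/2)*W stays exact: 3 criteria, alpha=0 -> gamma = 1500
        assert assess_gamma(np.array([[0]]), C=3, W=W)[0, 0] == 1500.0


class TestBeta:
    def test_worked_example_hand_values(self, worked):
        work = dominance_work(worked, W)
        beta = work.beta
        # g1 is never tied-or-worse-on-both vs anyone: only the self term
        assert beta[0] == 1000
        # g3 is dominated by g1, g2, g5, g6 (gamma 2W each) + self term
        assert beta[2] == 1000 + 4 * 2000
        assert (beta >= 1000).all()          # beta floor (C/2)W
        assert (beta >= np.diag(work.gamma)).all()

    def test_single_alternative_self_term_only(self):
        table = CriteriaTable(["solo"], [[1.0, 2.0]], ["c1", "c2"])
        assert dominance_work(table, W).beta[0] == 1000

    def test_beta_sums_requires_square(self):
        with pytest.raises(ValueError, match="square"):
            beta_sums(np.zeros((2, 3)))


class TestParetoFrontier:
    def test_worked_example_membership(self, worked):
        result = pareto_frontier(worked, W)
        assert result.frontier_ids == ["g1", "g5", "g6"]
        assert result.beta["g1"] == 1000.0
        assert result.beta["g3"] == 9000.0

    def test_membership_iff_beta_at_floor(self, worked):
        result = pareto_frontier(worked, W)
        on = {g for g in worked.ids if result.beta[g] == 1000.0}
        assert on == set(result.frontier_ids)

    def test_single_alternative_is_frontier(self):
        table = CriteriaTable(["solo"], [[5.0, 5.0]], ["c1", "c2"])
        assert pareto_frontier(table).frontier_ids == ["solo"]

    def test_rejects_small_penalty(self, worked):
        with pytest.raises(ValueError, match="penalty"):
            pareto_frontier(worked, W=2)

    def test_rejects_empty_table(self):
        with pytest.raises(ValueError):
            CriteriaTable([], np.empty((0, 2)), ["c1", "c2"])

    def test_finder_estimator_api(self, worked):
        finder = ParetoFrontierFinder(penalty=W)
        assert finder.get_params()["penalty"] == W
        finder.set_params(n_layers=2).fit(worked.values)
        assert finder.threshold_ == 2000
        assert list(finder.get_support(indices=True)) == [0, 4, 5]
        assert (finder.layers_[finder.frontier_mask_] == 0).all()


class TestDuplicates:
    def duplicate_table(self):
        return CriteriaTable(["a", "b", "c"], [[3, 3], [3, 3], [9, 9]],
                             ["c1", "c2"])

    def test_collapsed_duplicates_stay_on_frontier(self):
        result = pareto_frontier(self.duplicate_table())
        assert result.frontier_ids == ["a", "b"]
        assert result.duplicate_groups == [["a", "b"]]

    def test_strict_mode_drops_whole_duplicate_group(self):
        result = pareto_frontier(self.duplicate_table(),
                                 collapse_duplicates=False)
        assert result.frontier_ids == []
        assert result.duplicate_groups == [["a", "b"]]

    def test_brute_force_retains_identical_vectors(self):
        result = brute_force_frontier(self.duplicate_table())
        assert result.frontier_ids == ["a", "b"]


class TestBruteForce:
    def test_worked_example(self, worked):
        assert brute_force_frontier(worked).frontier_ids == ["g1", "g5", "g6"]

    def test_componentwise_minimum_dominates_everything(self):
        rng = np.random.default_rng(5)
        values = rng.uniform(1, 2, size=(30, 3))
        values[17] = 0.5
        table = CriteriaTable([f"a{i}" for i in range(30)], values,
                              ["x", "y", "z"])
        assert brute_force_frontier(table).frontier_ids == ["a17"]


class TestTournament:
    def test_worked_example_partition_two(self, worked):
        result = tournament_frontier(worked, partition_size=2, W=W)
        assert result.frontier_ids == ["g1", "g5", "g6"]

    def test_partition_larger_than_n_is_direct(self, worked):
        result = tournament_frontier(worked, partition_size=10, W=W)
        assert result.frontier_ids == pareto_frontier(worked, W).frontier_ids

    def test_partition_and_order_invariance(self):
        rng = np.random.default_rng(23)
        table = random_table(rng, 300, 2)
        reference = set(pareto_frontier(table).frontier_ids)
        for size in (50, 101, 299):
            assert set(tournament_frontier(table, size).frontier_ids) == reference
        for _ in range(5):
            perm = rng.permutation(table.n)
            shuffled = table.subset(perm)
            assert set(tournament_frontier(shuffled, 64).frontier_ids) == reference

    def test_rejects_partition_size_below_two(self, worked):
        with pytest.raises(ValueError, match="partition_size"):
            tournament_frontier(worked, partition_size=1)


class TestPeeling:
    def test_worked_example_layers(self, worked):
        layers = peel_frontiers(worked, layers=3, W=W)
        assert [l.frontier_ids for l in layers] == [
            ["g1", "g5", "g6"], ["g2"], ["g3", "g4"]]
        assert [l.layer for l in layers] == [0, 1, 2]

    def test_layer_one_matches_brute_force_on_remainder(self, worked):
        layers = peel_frontiers(worked, layers=2, W=W)
        remainder = worked.subset([1, 2, 3])  # g2, g3, g4
        assert set(layers[1].frontier_ids) == \
            set(brute_force_frontier(remainder).frontier_ids)

    def test_incomparable_set_is_single_layer(self):
        # anti-chain: each alternative best on a different criterion
        table = CriteriaTable(["a", "b", "c"], [[1, 3], [2, 2], [3, 1]],
                              ["c1", "c2"])
        layers = peel_frontiers(table, layers=3)
        assert len(layers) == 1
        assert layers[0].frontier_ids == ["a", "b", "c"]

    def test_total_order_peels_one_per_layer(self):
        table = CriteriaTable(["a", "b", "c"], [[1, 1], [2, 2], [3, 3]],
                              ["c1", "c2"])
        layers = peel_frontiers(table, layers=5)
        assert [l.frontier_ids for l in layers] == [["a"], ["b"], ["c"]]

    def test_layers_partition_the_ids(self):
        rng = np.random.default_rng(9)
        table = random_table(rng, 60, 3)
        layers = peel_frontiers(table, layers=60)
        seen = [g for l in layers for g in l.frontier_ids]
        assert sorted(seen) == sorted(table.ids)
        assert len(seen) == len(set(seen))

    def test_rejects_nonpositive_layers(self, worked):
        with pytest.raises(ValueError, match="layers"):
            peel_frontiers(worked, layers=0)


class TestCriteriaTableIO:
    def test_tsv_round_trip(self, worked, tmp_path):
        path = tmp_path / "criteria.tsv"
        worked.write_tsv(path)
        back = CriteriaTable.read_tsv(path)
        assert back.ids == worked.ids
        assert back.criterion_names == worked.criterion_names
        np.testing.assert_array_equal(back.values, worked.values)

    def test_unique_ids_required(self):
        with pytest.raises(ValueError, match="unique"):
            CriteriaTable(["a", "a"], [[1, 2], [3, 4]], ["c1", "c2"])
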