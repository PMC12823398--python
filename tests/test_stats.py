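"""Powerset genotype statistics, odds-ratio algebra and interaction tests."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats as sps
from scipy.special import comb

from perturbmap.stats import (interaction_test, marginal_frequencies,
                              null_expected_distribution, order_distribution,
                              p_observed_gt_expected, pairwise_or,
                              powerset_aggregate, replicate_concordance,
                              _state_counts)


def draws_from_cell_probs(p4, n_draws, n_nodules, seed=0):
    """Binary 2-plasmid draws with joint cell probabilities (p00,p01,p10,p11)."""
    rng = np.random.default_rng(seed)
    cells = rng.choice(4, size=(n_draws, n_nodules), p=p4)
    a = (cells >= 2).astype(np.uint8)
    b = (cells % 2).astype(np.uint8)
    return np.stack([a, b], axis=2)


class TestPowerset:
    def test_8_plasmids_enumerate_256_states(self):
        rng = np.random.default_rng(0)
        draws = (rng.random((10, 30, 8)) < 0.5).astype(np.uint8)
        table = powerset_aggregate(draws)
        assert len(table) == 256

    def test_all_zero_draws_mass_on_empty_genotype(self):
        draws = np.zeros((5, 12, 4), dtype=np.uint8)
        table = powerset_aggregate(draws)
        assert table.loc[0, "median"] == 12
        assert table.loc[1:, "median"].sum() == 0

    def test_counts_match_hand_enumeration(self):
        # one draw, 3 plasmids, explicit genotypes
        genotypes = np.array([
            [0, 0, 0], [1, 0, 0], [1, 0, 0], [0, 1, 1], [1, 1, 1]])
        draws = genotypes[None, :, :].astype(np.uint8)
        counts = _state_counts(draws)[0]
        expected = np.zeros(8, dtype=int)
        expected[0] = 1          # 000
        expected[1] = 2          # 100 -> bit0
        expected[6] = 1          # 011 -> bits 1+2
        expected[7] = 1          # 111
        np.testing.assert_array_equal(counts, expected)

    def test_counts_sum_to_nodules(self):
        rng = np.random.default_rng(1)
        draws = (rng.random((20, 17, 5)) < 0.3).astype(np.uint8)
        counts = _state_counts(draws)
        np.testing.assert_array_equal(counts.sum(axis=1), 17)


class TestOrderDistribution:
    def test_all_ones_mass_at_full_order(self):
        draws = np.ones((4, 9, 6), dtype=np.uint8)
        table = order_distribution(draws)
        assert table.loc[6, "mean"] == 1.0
        assert table.loc[:5, "mean"].sum() == 0.0

    def test_frequencies_sum_to_one(self):
        rng = np.random.default_rng(2)
        draws = (rng.random((10, 40, 8)) < 0.4).astype(np.uint8)
        table = order_distribution(draws)
        assert table["mean"].sum() == pytest.approx(1.0)

    def test_binomial_reference_closed_form(self):
        draws = np.zeros((1, 2, 8), dtype=np.uint8)
        table = order_distribution(draws)
        assert table.loc[4, "binomial_reference"] == pytest.approx(
            comb(8, 4) / 256)
        assert table["binomial_reference"].sum() == pytest.approx(1.0)

    def test_unbiased_draws_match_binomial(self):
        rng = np.random.default_rng(3)
        draws = (rng.random((50, 2000, 8)) < 0.5).astype(np.uint8)
        table = order_distribution(draws)
        np.testing.assert_allclose(table["mean"],
                                   table["binomial_reference"], atol=0.01)


class TestMarginals:
    def test_constant_presence(self):
        assert marginal_frequencies(
            np.ones((3, 5, 2), dtype=np.uint8))["mean"].tolist() == [1.0, 1.0]
        assert marginal_frequencies(
            np.zeros((3, 5, 2), dtype=np.uint8))["mean"].tolist() == [0.0, 0.0]

    def test_matches_direct_average_and_sorted(self):
        rng = np.random.default_rng(4)
        draws = (rng.random((8, 30, 4)) < rng.random(4)).astype(np.uint8)
        table = marginal_frequencies(draws)
        direct = dict(zip([f"p{g}" for g in range(4)], draws.mean(axis=(0, 1))))
        for _, row in table.iterrows():
            assert row["mean"] == pytest.approx(direct[row["plasmid"]])
        assert list(table["mean"]) == sorted(table["mean"], reverse=True)


class TestNullDistribution:
    def test_reproducible(self):
        rng = np.random.default_rng(5)
        draws = (rng.random((10, 20, 3)) < 0.5).astype(np.uint8)
        a = null_expected_distribution(draws, n_sim=50, seed=9)
        b = null_expected_distribution(draws, n_sim=50, seed=9)
        np.testing.assert_array_equal(a, b)

    def test_single_plasmid_marginals(self):
        draws = np.zeros((5, 10, 3), dtype=np.uint8)
        draws[:, :, 0] = 1
        null = null_expected_distribution(draws, n_sim=100, seed=0)
        # all nodules in the state with only plasmid 0 (bitmask 1)
        assert (null[:, 1] == 10).all()

    def test_uniform_marginals_symmetric_states(self):
        # marginals 0.5 everywhere: all states equally likely under H0
        rng = np.random.default_rng(6)
        draws = (rng.random((200, 300, 3)) < 0.5).astype(np.uint8)
        null = null_expected_distribution(draws, n_sim=2000, seed=1)
        means = null.mean(axis=0)
        np.testing.assert_allclose(means, 300 / 8, rtol=0.05)


class TestPObservedGtExpected:
    def test_identical_distributions_give_half(self):
        counts = np.tile(np.array([[3, 2, 1, 0]]), (100, 1))
        p = p_observed_gt_expected(counts, counts.copy())
        np.testing.assert_allclose(p, 0.5)

    def test_dominating_observed_gives_one(self):
        obs = np.full((50, 4), 10)
        null = np.full((50, 4), 2)
        np.testing.assert_allclose(p_observed_gt_expected(obs, null), 1.0)

    def test_partition_of_unity(self):
        rng = np.random.default_rng(7)
        obs = rng.integers(0, 5, (60, 8))
        null = rng.integers(0, 5, (60, 8))
        p_gt = p_observed_gt_expected(obs, null, seed=1)
        p_lt = p_observed_gt_expected(null, obs, seed=1)
        # with the same pairing permutations, p(O>E) + p(E>O) + ties = 1
        # and each p carries half the tie mass
        np.testing.assert_allclose(p_gt + p_lt, 1.0)


class TestPairwiseOr:
    def test_independence_gives_unit_or(self):
        draws = draws_from_cell_probs([0.25] * 4, 1, 4000, seed=0)
        # exact table: construct deterministic counts instead
        genotypes = np.repeat(np.array([[0, 0], [0, 1], [1, 0], [1, 1]]),
                              25, axis=0)
        res = pairwise_or(genotypes[None].astype(np.uint8), 0, 1)
        assert res.or_median == pytest.approx(1.0)
        assert res.theta_11 == pytest.approx(0.0, abs=1e-12)

    def test_known_table_gives_or_16(self):
        reps = np.array([4, 1, 1, 4]) * 10
        cells = np.concatenate([np.full(r, i) for i, r in enumerate(reps)])
        a = (cells >= 2).astype(np.uint8)
        b = (cells % 2).astype(np.uint8)
        draws = np.stack([a, b], axis=1)[None]
        res = pairwise_or(draws, 0, 1)
        assert res.or_median == pytest.approx(16.0)
        assert res.theta_11 == pytest.approx(np.log(16.0))

    def test_degenerate_column_is_missing(self):
        draws = np.zeros((3, 10, 2), dtype=np.uint8)
        draws[:, :, 1] = np.random.default_rng(0).integers(0, 2, (3, 10))
        res = pairwise_or(draws, 0, 1)
        assert np.isnan(res.or_median)

    def test_zero_cell_flagged_and_corrected(self):
        genotypes = np.array([[0, 0], [0, 1], [1, 0], [1, 0], [1, 1]])
        draws = np.tile(genotypes, (1, 1, 1)).astype(np.uint8)
        draws = genotypes[None].astype(np.uint8)
        draws[0, 0] = [1, 1]  # remove the 00 cell
        res = pairwise_or(draws, 0, 1)
        assert res.continuity_corrected

    def test_softmax_log2_interaction_recovered(self):
        theta11 = np.log(2.0)
        weights = np.exp([0.0, 0.0, 0.0, theta11])
        p4 = weights / weights.sum()
        draws = draws_from_cell_probs(p4, 400, 500, seed=1)
        res = pairwise_or(draws, 0, 1)
        assert res.or_lo < 2.0 < res.or_hi
        assert res.or_median == pytest.approx(2.0, rel=0.25)


@settings(max_examples=40, deadline=None)
@given(st.integers(0, 2**31 - 1))
def test_or_symmetries(seed):
    """Swapping plasmids preserves the OR; complementing one inverts it."""
    rng = np.random.default_rng(seed)
    # odd number of draws so the median is a single order statistic
    draws = (rng.random((5, 40, 2)) < rng.uniform(0.2, 0.8, 2)).astype(np.uint8)
    res = pairwise_or(draws, 0, 1)
    if np.isnan(res.or_median) or res.continuity_corrected:
        return
    swapped = pairwise_or(draws[:, :, ::-1].copy(), 0, 1)
    assert swapped.or_median == pytest.approx(res.or_median)
    flipped = draws.copy()
    flipped[:, :, 0] = 1 - flipped[:, :, 0]
    inv = pairwise_or(flipped, 0, 1)
    if not inv.continuity_corrected:
        assert inv.or_median == pytest.approx(1.0 / res.or_median)


class TestInteractionTest:
    def test_exactly_null_table_gives_p_near_one(self):
        # margins 0.5/0.5, double-positive exactly at independence
        genotypes = np.repeat(np.array([[0, 0], [0, 1], [1, 0], [1, 1]]),
                              25, axis=0)
        res = interaction_test(genotypes[None].astype(np.uint8), 0, 1,
                               n_sim=2000, seed=0)
        assert res.p_value > 0.8

    def test_power_against_strong_interaction(self):
        theta11 = np.log(4.0)
        weights = np.exp([0.0, 0.0, 0.0, theta11])
        p4 = weights / weights.sum()
        hits = 0
        reps = 20
        for rep in range(reps):
            draws = draws_from_cell_probs(p4, 1, 300, seed=100 + rep)
            res = interaction_test(draws, 0, 1, n_sim=1000, seed=rep)
            hits += res.p_value < 0.05
        assert hits >= 0.8 * reps

    def test_null_p_values_roughly_uniform(self):
        ps = []
        for rep in range(100):
            draws = draws_from_cell_probs([0.25] * 4, 1, 300, seed=500 + rep)
            res = interaction_test(draws, 0, 1, n_sim=400, seed=rep)
            ps.append(res.p_value)
        assert sps.kstest(ps, "uniform").pvalue > 0.01


class TestReplicateConcordance:
    def test_identical_inputs_give_unit_correlation(self):
        rng = np.random.default_rng(8)
        P = rng.random((20, 3))
        table = replicate_concordance(P, P.copy())
        np.testing.assert_allclose(table["pearson_r"], 1.0)

    def test_anticorrelated_inputs(self):
        x = np.linspace(0, 1, 30)
        P_a = np.stack([x, x], axis=1)
        P_b = np.stack([1 - x, 1 - x], axis=1)
        table = replicate_concordance(P_a, P_b)
        np.testing.assert_allclose(table["pearson_r"], -1.0)

    def test_independent_inputs_near_zero(self):
        rng = np.random.default_rng(9)
        table = replicate_concordance(rng.random((200, 4)), rng.random((200, 4)))
        assert np.abs(table["pearson_r"]).max() < 0.2

    def test_too_few_pairs_missing(self):
        rng = np.random.default_rng(10)
        table = replicate_concordance(rng.random((2, 2)), rng.random((2, 2)))
        assert table["pearson_r"].isna().all()
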