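"""Nonparametric battery: scipy-backed tests against independent oracles."""

import itertools

import numpy as np
import pytest
from scipy.stats import rankdata

from dipa.cohort import ClassMMEModel
from dipa.errors import InsufficientDataError, ValidationError
from dipa.stats import (
    ipa_by_gender,
    kendall_tau,
    kruskal_wallis,
    mann_whitney,
    shapiro_wilk,
    spearman_rho,
)


def mann_whitney_exact_oracle(a, b):
    """Exact two-sided Mann-Whitney by enumerating all rank assignments.

    Enumerates every C(n1+n2, n1) way the pooled ranks could be split
    between the groups (the null distribution for untied data) and counts
    tail probabilities directly.  Independent of scipy's implementation.
    """
    pooled = np.concatenate([a, b])
    n1, n2 = len(a), len(b)
    ranks = rankdata(pooled)

    def u_of(idx):
        return ranks[list(idx)].sum() - n1 * (n1 + 1) / 2

    u_obs = u_of(range(n1))
    us = np.array(
        [u_of(c) for c in itertools.combinations(range(n1 + n2), n1)]
    )
    p_le = np.mean(us <= u_obs)
    p_ge = np.mean(us >= u_obs)
    return u_obs, min(1.0, 2 * min(p_le, p_ge))


def kruskal_hand_oracle(*groups):
    """Kruskal-Wallis H from first principles (no tie correction needed
    for untied inputs): H = 12/(N(N+1)) * sum(R_i^2/n_i) - 3(N+1)."""
    pooled = np.concatenate(groups)
    ranks = rankdata(pooled)
    n_total = len(pooled)
    h = 0.0
    start = 0
    for g in groups:
        r = ranks[start:start + len(g)].sum()
        h += r**2 / len(g)
        start += len(g)
    return 12 / (n_total * (n_total + 1)) * h - 3 * (n_total + 1)


class TestShapiroWilk:
    def test_too_small_sample_rejected(self):
        with pytest.raises(InsufficientDataError):
            shapiro_wilk([1.0, 2.0])

    def test_constant_sample_rejected(self):
        with pytest.raises(InsufficientDataError):
            shapiro_wilk([3.0] * 10)

    def test_detects_uniform_nonnormality(self):
        # power check: uniform data at n=50 rejects in ~74% of replicates
        # (rate frozen from a 5000-replicate simulation; bound is ~2 SE below)
        rng = np.random.default_rng(101)
        rejections = sum(
            shapiro_wilk(rng.uniform(0, 1, 50)).p_value < 0.05 for _ in range(100)
        )
        assert rejections >= 65

    def test_null_pvalues_uniform(self):
        # under normality the p-value distribution is uniform
        from scipy.stats import kstest

        rng = np.random.default_rng(202)
        pvals = [shapiro_wilk(rng.normal(size=500)).p_value for _ in range(200)]
        assert kstest(pvals, "uniform").pvalue > 0.01


class TestKruskalWallis:
    def test_identical_groups_no_separation(self):
        res = kruskal_wallis([1, 2, 3], [1, 2, 3], [1, 2, 3])
        assert res.statistic == pytest.approx(0.0, abs=1e-12)
        assert res.p_value == pytest.approx(1.0)

    def test_all_tied_observations(self):
        res = kruskal_wallis([5, 5], [5, 5, 5])
        assert res.statistic == 0.0 and res.p_value == 1.0

    def test_two_tiny_groups_match_hand_ranks(self):
        res = kruskal_wallis([1, 2], [3, 4])
        assert res.statistic == pytest.approx(kruskal_hand_oracle([1, 2], [3, 4]))
        assert res.statistic == pytest.approx(2.4)  # 0.6*(4.5+24.5)-15

    def test_random_untied_groups_match_hand_oracle(self):
        rng = np.random.default_rng(7)
        a, b, c = rng.normal(size=(3, 12))
        res = kruskal_wallis(a, b, c)
        assert res.statistic == pytest.approx(kruskal_hand_oracle(a, b, c))

    def test_separates_the_three_class_mme_distributions(self):
        rng = np.random.default_rng(8)
        c = ClassMMEModel(16.34, 2.3, 30.0).sample(50, rng)
        d = ClassMMEModel(45.39, 33.75, 67.5).sample(50, rng)
        e = ClassMMEModel(94.09, 80.0, 135.0).sample(50, rng)
        res = kruskal_wallis(c, d, e, labels=("C", "D", "E"))
        assert res.p_value < 0.001

    def test_empty_group_rejected(self):
        with pytest.raises(ValidationError):
            kruskal_wallis([1, 2], [])

    def test_two_groups_consistent_with_mann_whitney(self):
        # same rank basis: the two p-values agree up to the continuity term
        rng = np.random.default_rng(9)
        a, b = rng.normal(size=(2, 30)), rng.normal(0.3, 1, size=(2, 30))
        for x, y in zip(a, b):
            p_kw = kruskal_wallis(x, y).p_value
            p_mw = mann_whitney(x, y).p_value
            assert abs(p_kw - p_mw) <= 0.02


class TestMannWhitney:
    def test_identical_samples_p_one(self):
        res = mann_whitney([1, 2, 3, 4], [1, 2, 3, 4])
        assert res.p_value == pytest.approx(1.0, abs=0.02)

    def test_fully_separated_tiny_groups(self):
        res = mann_whitney([1, 2, 3], [4, 5, 6])
        assert res.statistic == 0.0
        assert res.p_value == pytest.approx(0.1)  # 2/20 orderings as extreme
        assert res.extra["method"] == "exact"

    def test_exact_branch_matches_enumeration_oracle(self):
        rng = np.random.default_rng(10)
        for _ in range(20):
            n1, n2 = rng.integers(2, 9, size=2)
            a = rng.normal(size=n1)
            b = rng.normal(0.5, 1, size=n2)
            res = mann_whitney(a, b)
            u_oracle, p_oracle = mann_whitney_exact_oracle(list(a), list(b))
            assert res.statistic == pytest.approx(u_oracle)
            assert res.p_value == pytest.approx(p_oracle, abs=1e-12)

    def test_exact_and_asymptotic_agree_at_n8(self):
        rng = np.random.default_rng(12)
        for _ in range(20):
            a, b = rng.normal(size=(2, 8))
            _, p_exact = mann_whitney_exact_oracle(list(a), list(b))
            from scipy.stats import mannwhitneyu

            p_asym = mannwhitneyu(a, b, alternative="two-sided",
                                  method="asymptotic").pvalue
            assert abs(p_exact - p_asym) <= 0.02

    def test_tied_data_falls_back_to_asymptotic(self):
        res = mann_whitney([1, 1, 2], [2, 3, 3])
        assert res.extra["method"] == "asymptotic"
        assert 0 <= res.p_value <= 1

    def test_empty_input_rejected(self):
        with pytest.raises(ValidationError):
            mann_whitney([], [1.0])


class TestSpearman:
    def test_perfectly_monotone(self):
        assert spearman_rho([1, 2, 3, 4], [10, 20, 30, 40]).statistic == pytest.approx(1.0)

    def test_reversed_monotone(self):
        assert spearman_rho([1, 2, 3, 4], [40, 30, 20, 10]).statistic == pytest.approx(-1.0)

    def test_hand_computed_rank_differences(self):
        # d = (1-2, 2-1, 3-4, 4-3); rho = 1 - 6*4/(4*15) = 0.6
        assert spearman_rho([1, 2, 3, 4], [2, 1, 4, 3]).statistic == pytest.approx(0.6)

    def test_class_letters_map_to_ordinals(self):
        res = spearman_rho(["A", "B", "C", "D", "E"], [0, 0, 16, 45, 94])
        assert res.statistic == pytest.approx(
            spearman_rho([0, 1, 2, 3, 4], [0, 0, 16, 45, 94]).statistic
        )

    def test_invariant_under_strictly_monotone_transform(self):
        rng = np.random.default_rng(13)
        x = rng.normal(size=25)
        y = x + rng.normal(size=25)
        base = spearman_rho(x, y).statistic
        assert spearman_rho(np.exp(x), y).statistic == pytest.approx(base)
        assert spearman_rho(x, y**3).statistic == pytest.approx(base)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValidationError):
            spearman_rho([1, 2, 3], [1, 2])

    def test_kendall_companion_runs(self):
        res = kendall_tau([1, 2, 3, 4], [1, 3, 2, 4])
        assert -1 <= res.statistic <= 1


class TestIPAByGender:
    def test_both_methods_run(self):
        rng = np.random.default_rng(14)
        ipa = rng.integers(0, 3, 100)
        gender = np.where(rng.random(100) < 0.45, "male", "female")
        for method in ("mann-whitney", "chi2"):
            res = ipa_by_gender(ipa, gender, method=method)
            assert 0 <= res.p_value <= 1

    def test_needs_exactly_two_levels(self):
        with pytest.raises(ValidationError):
            ipa_by_gender([0, 1], ["a", "a"])
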