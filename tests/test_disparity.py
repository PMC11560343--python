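import itertools
import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from jawdisp.disparity import (
    bonferroni_adjust,
    bootstrap_disparity,
    compare_disparities,
    mann_whitney_u,
    pairwise_group_means,
    pearson_correlation,
    sum_of_variances,
)
from jawdisp.errors import InputError


def scores_frame(arr):
    arr = np.asarray(arr, dtype=float)
    return pd.DataFrame(
        arr,
        index=[f"sp{i}" for i in range(arr.shape[0])],
        columns=[f"PC{j + 1}" for j in range(arr.shape[1])],
    )


class TestSumOfVariances:
    def test_two_points(self):
        s = scores_frame([[0, 0], [2, 0]])
        assert sum_of_variances(s) == pytest.approx(2.0)

    def test_identical_points_zero(self):
        s = scores_frame([[1, 1], [1, 1], [1, 1]])
        assert sum_of_variances(s) == 0.0

    def test_single_point_warns_zero(self):
        s = scores_frame([[1, 2], [3, 4]])
        with pytest.warns(UserWarning):
            assert sum_of_variances(s, ["sp0"]) == 0.0

    def test_three_points_hand_value(self):
        s = scores_frame([[0, 0], [1, 1], [2, 0]])
        # per-axis sample variances: 1 and 1/3
        assert sum_of_variances(s) == pytest.approx(1.0 + 1.0 / 3.0)

    def test_unknown_species_named(self):
        s = scores_frame([[0, 0], [1, 1]])
        with pytest.raises(InputError, match="ghost"):
            sum_of_variances(s, ["sp0", "ghost"])

    def test_rotation_invariance(self, rng):
        x = rng.normal(size=(20, 3))
        q, _ = np.linalg.qr(rng.normal(size=(3, 3)))
        assert sum_of_variances(scores_frame(x)) == pytest.approx(
            sum_of_variances(scores_frame(x @ q)), rel=1e-9
        )

    def test_full_sample_equals_eigenvalue_sum(self, rng):
        from jawdisp.ordination import pca

        t = pd.DataFrame(rng.normal(size=(25, 5)), index=[f"s{i}" for i in range(25)])
        ord_ = pca(t)
        assert sum_of_variances(ord_.scores) == pytest.approx(
            ord_.eigenvalues.sum(), abs=1e-9
        )


class TestBootstrap:
    def test_replicate_count(self, rng):
        s = scores_frame(rng.normal(size=(10, 3)))
        reps = bootstrap_disparity(s, s.index, n_boot=100, seed=0)
        assert reps.shape == (100,)

    def test_identical_rows_all_zero(self):
        s = scores_frame(np.ones((6, 2)))
        assert np.all(bootstrap_disparity(s, s.index, 50, seed=0) == 0.0)

    def test_seed_reproducibility(self, rng):
        s = scores_frame(rng.normal(size=(12, 4)))
        a = bootstrap_disparity(s, s.index, 200, seed=42)
        b = bootstrap_disparity(s, s.index, 200, seed=42)
        c = bootstrap_disparity(s, s.index, 200, seed=43)
        assert np.array_equal(a, b)
        assert not np.array_equal(a, c)

    def test_plugin_bias(self, rng):
        # E[replicate] = ((n-1)/n) * point estimate (bootstrap plug-in bias)
        n = 12
        s = scores_frame(rng.normal(size=(n, 3)))
        point = sum_of_variances(s)
        reps = bootstrap_disparity(s, s.index, n_boot=10000, seed=7)
        mc_se = reps.std(ddof=1) / math.sqrt(len(reps))
        assert abs(reps.mean() - (n - 1) / n * point) < 3 * mc_se

    def test_invalid_n_boot(self):
        s = scores_frame(np.ones((4, 2)))
        with pytest.raises(InputError):
            bootstrap_disparity(s, s.index, 0, seed=0)


class TestMannWhitney:
    def test_small_separated(self):
        u, p = mann_whitney_u([1, 2], [3, 4])
        assert u == 0
        assert p == pytest.approx(1 / 3)  # 2 / C(4, 2) labelings

    def test_three_vs_three_separated(self):
        u, p = mann_whitney_u([1, 2, 3], [4, 5, 6])
        assert u == 0
        assert p == pytest.approx(0.1)  # 2 / C(6, 3)

    def test_identical_samples_p_one(self):
        _, p = mann_whitney_u([1, 2, 3], [1, 2, 3])
        assert p == pytest.approx(1.0, abs=1e-9)

    def test_empty_sample(self):
        with pytest.raises(InputError):
            mann_whitney_u([], [1.0])

    def test_exact_matches_scipy(self, rng):
        for _ in range(25):
            nx, ny = rng.integers(2, 7, size=2)
            x = rng.normal(size=nx)
            y = rng.normal(size=ny)
            u, p = mann_whitney_u(x, y)
            ref = stats.mannwhitneyu(x, y, alternative="two-sided", method="exact")
            assert u == pytest.approx(ref.statistic)
            assert p == pytest.approx(ref.pvalue, abs=1e-12)

    def test_exact_vs_normal_agree(self, rng):
        # tie-free pooled sizes 10-12 (each group >= 5): both routes within 0.02
        for _ in range(50):
            nx = int(rng.integers(5, 8))
            ny = int(rng.integers(5, 13 - nx))
            x, y = rng.normal(size=nx), rng.normal(0.5, 1, size=ny)
            u, p_exact = mann_whitney_u(x, y, exact_limit=12)
            _, p_norm = mann_whitney_u(x, y, exact_limit=0)
            assert abs(p_exact - p_norm) < 0.02

    def test_large_sample_normal_approx(self, rng):
        x, y = rng.normal(size=40), rng.normal(1.0, 1, size=40)
        u, p = mann_whitney_u(x, y)
        ref = stats.mannwhitneyu(x, y, alternative="two-sided", method="asymptotic")
        assert u == pytest.approx(ref.statistic)
        assert p == pytest.approx(ref.pvalue, rel=1e-6)


class TestBonferroni:
    def test_basic(self):
        assert bonferroni_adjust([0.01], m=3)[0] == pytest.approx(0.03)

    def test_capped(self):
        assert bonferroni_adjust([0.5], m=4)[0] == 1.0

    def test_identity(self):
        assert bonferroni_adjust([0.2], m=1)[0] == pytest.approx(0.2)

    def test_out_of_range(self):
        with pytest.raises(InputError):
            bonferroni_adjust([1.5], m=1)

    def test_m_too_small(self):
        with pytest.raises(InputError):
            bonferroni_adjust([0.1, 0.2], m=1)


class TestCompareDisparities:
    def _two_group_scores(self, rng, n=30, sd_ratio=2.0, axes=4):
        a = rng.normal(0, 1, size=(n, axes))
        b = rng.normal(0, sd_ratio, size=(n, axes))
        scores = scores_frame(np.vstack([a, b]))
        grouping = pd.Series(
            ["narrow"] * n + ["wide"] * n, index=scores.index, name="group"
        )
        return scores, grouping

    def test_constructed_effect(self, rng):
        scores, grouping = self._two_group_scores(rng)
        res = compare_disparities(scores, grouping, n_boot=100, seed=5)
        g = res.groups.set_index("group")
        assert g.loc["wide", "disparity"] > g.loc["narrow", "disparity"]
        assert res.pairs["p_adj"].iloc[0] < 0.001

    def test_self_comparison_p_near_one(self, rng):
        x = rng.normal(size=(15, 3))
        scores = scores_frame(np.vstack([x, x]))
        grouping = pd.Series(["a"] * 15 + ["b"] * 15, index=scores.index)
        res = compare_disparities(scores, grouping, n_boot=200, seed=3)
        assert res.pairs["p_adj"].iloc[0] > 0.5

    def test_degenerate_groups_flagged(self):
        scores = scores_frame(np.ones((8, 2)))
        grouping = pd.Series(["a"] * 4 + ["b"] * 4, index=scores.index)
        res = compare_disparities(scores, grouping, n_boot=20, seed=0)
        assert res.groups["disparity"].eq(0).all()
        assert bool(res.pairs["degenerate"].iloc[0])
        assert math.isnan(res.pairs["p_raw"].iloc[0])

    def test_small_group_excluded_with_warning(self, rng):
        x = rng.normal(size=(14, 2))
        scores = scores_frame(x)
        grouping = pd.Series(["a"] * 6 + ["b"] * 6 + ["tiny"] * 2, index=scores.index)
        with pytest.warns(UserWarning, match="tiny"):
            res = compare_disparities(scores, grouping, n_boot=20, seed=0)
        assert set(res.pairs[["group_a", "group_b"]].to_numpy().ravel()) == {"a", "b"}
        tiny = res.groups.set_index("group").loc["tiny"]
        assert not tiny["tested"] and tiny["n"] == 2

    def test_too_few_groups(self, rng):
        scores = scores_frame(rng.normal(size=(5, 2)))
        grouping = pd.Series(["a"] * 4 + ["b"], index=scores.index)
        with pytest.raises(InputError):
            compare_disparities(scores, grouping, n_boot=10, seed=0)

    def test_bonferroni_over_pairs(self, rng):
        scores = scores_frame(rng.normal(size=(30, 3)))
        grouping = pd.Series(
            ["a"] * 10 + ["b"] * 10 + ["c"] * 10, index=scores.index
        )
        res = compare_disparities(scores, grouping, n_boot=50, seed=0)
        assert len(res.pairs) == 3
        expected = np.minimum(1.0, res.pairs["p_raw"] * 3)
        assert np.allclose(res.pairs["p_adj"], expected)


class TestPairwiseGroupMeans:
    def test_identical_groups(self):
        table = pairwise_group_means([1, 2, 3, 1, 2, 3], ["a"] * 3 + ["b"] * 3)
        row = table.iloc[0]
        assert row["t"] == pytest.approx(0.0)
        assert row["p_adj"] == pytest.approx(1.0)

    def test_hand_computed_t(self):
        table = pairwise_group_means([1, 2, 3, 4, 5, 6], ["a"] * 3 + ["b"] * 3)
        row = table.iloc[0]
        expected_t = -3 / math.sqrt(2.0 / 3.0)  # pooled SD = 1, df = 4
        assert row["t"] == pytest.approx(expected_t)
        assert row["df"] == 4
        assert row["p_raw"] == pytest.approx(2 * stats.t.sf(abs(expected_t), 4))

    def test_three_groups_bonferroni_times_three(self, rng):
        values = rng.normal(size=18)
        groups = ["a"] * 6 + ["b"] * 6 + ["c"] * 6
        table = pairwise_group_means(values, groups)
        assert len(table) == 3
        assert np.allclose(
            table["p_adj"], np.minimum(1.0, table["p_raw"] * 3)
        )

    def test_undersized_group_excluded(self, rng):
        values = np.concatenate([rng.normal(size=5), rng.normal(size=5), [9.0]])
        groups = ["a"] * 5 + ["b"] * 5 + ["lone"]
        with pytest.warns(UserWarning, match="lone"):
            table = pairwise_group_means(values, groups)
        assert len(table) == 1

    def test_matches_r_style_pooled_sd(self, rng):
        # oracle: statsmodels-free pooled computation repeated independently
        vals = rng.normal(size=15)
        groups = np.array(["a"] * 5 + ["b"] * 5 + ["c"] * 5)
        table = pairwise_group_means(vals, groups).set_index(["group_a", "group_b"])
        resid = np.concatenate(
            [vals[groups == g] - vals[groups == g].mean() for g in "abc"]
        )
        pooled_sd = math.sqrt((resid**2).sum() / (15 - 3))
        for ga, gb in itertools.combinations("abc", 2):
            diff = vals[groups == ga].mean() - vals[groups == gb].mean()
            t = diff / (pooled_sd * math.sqrt(2 / 5))
            assert table.loc[(ga, gb), "t"] == pytest.approx(t)

    def test_welch_option(self, rng):
        x = np.concatenate([rng.normal(0, 1, 10), rng.normal(1, 5, 10)])
        groups = ["a"] * 10 + ["b"] * 10
        table = pairwise_group_means(x, groups, welch=True)
        ref = stats.ttest_ind(x[:10], x[10:], equal_var=False)
        assert table.iloc[0]["t"] == pytest.approx(ref.statistic)
        assert table.iloc[0]["p_raw"] == pytest.approx(ref.pvalue)


class TestPearson:
    def test_perfect_linear(self):
        x = np.arange(10.0)
        r, p = pearson_correlation(x, 2 * x + 1)
        assert r == pytest.approx(1.0)
        assert p == 0.0

    def test_hand_value_against_covariance_oracle(self):
        x = np.array([1.0, 2.0, 3.0, 4.0])
        y = np.array([1.0, -1.0, 1.0, -1.0])
        xc, yc = x - x.mean(), y - y.mean()
        oracle = (xc @ yc) / math.sqrt((xc @ xc) * (yc @ yc))
        r, p = pearson_correlation(x, y)
        assert r == pytest.approx(oracle)
        t = oracle * math.sqrt(2 / (1 - oracle**2))
        assert p == pytest.approx(2 * stats.t.sf(abs(t), 2))

    def test_matches_scipy(self, rng):
        x, y = rng.normal(size=30), rng.normal(size=30)
        r, p = pearson_correlation(x, y)
        ref = stats.pearsonr(x, y)
        assert r == pytest.approx(ref.statistic, abs=1e-12)
        assert p == pytest.approx(ref.pvalue, rel=1e-9)

    def test_insufficient_data(self):
        with pytest.raises(InputError):
            pearson_correlation([1.0, 2.0], [3.0, 4.0])

    def test_constant_input(self):
        with pytest.raises(InputError):
            pearson_correlation([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])
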