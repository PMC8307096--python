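"""Classical tests against hand-computed and closed-form oracles."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from gshcohort import (
    DegenerateInputError,
    anova_tukey,
    hierarchical_regression,
    median_split,
    pearson_chi2,
    spearman_corr,
    two_sample_t,
)


class TestChi2:
    def test_study_gender_counts(self):
        # CHR 11 male / 2 female vs HC 19 / 11
        r = pearson_chi2([[11, 2], [19, 11]])
        assert r.statistic == pytest.approx(1.948, abs=0.001)
        assert r.p_value == pytest.approx(0.163, abs=0.001)
        assert r.df == 1.0

    def test_homogeneous_proportions(self):
        r = pearson_chi2([[10, 10], [20, 20]])
        assert r.statistic == 0.0 and r.p_value == 1.0

    def test_perfect_separation_by_expected_counts(self):
        # expected counts are 2.5 in every cell: sum (O-E)^2/E = 4 * 6.25/2.5 = 10
        r = pearson_chi2([[5, 0], [0, 5]])
        assert r.statistic == pytest.approx(10.0)

    def test_zero_margin_rejected(self):
        with pytest.raises(DegenerateInputError):
            pearson_chi2([[0, 0], [3, 4]])

    @given(st.lists(st.integers(min_value=1, max_value=50), min_size=4, max_size=4))
    @settings(max_examples=50, derandomize=True)
    def test_transpose_invariance(self, cells):
        t = np.array(cells).reshape(2, 2)
        assert pearson_chi2(t).statistic == pytest.approx(pearson_chi2(t.T).statistic)


class TestTTest:
    def test_identical_groups(self):
        r = two_sample_t([1.0, 2, 3], [1.0, 2, 3])
        assert r.statistic == 0.0 and r.p_value == pytest.approx(1.0)

    def test_pooled_hand_computation(self):
        r = two_sample_t([1, 2, 3], [2, 3, 4], pooled=True)
        assert r.statistic == pytest.approx(-1.2247, abs=1e-4)
        assert r.df == 4.0
        assert r.estimate == pytest.approx(-1.0)

    def test_zero_variance_rejected(self):
        with pytest.raises(DegenerateInputError):
            two_sample_t([0.0, 0.0], [1.0, 1.0])

    def test_group_swap_symmetry(self, rng):
        a, b = rng.normal(0, 1, 15), rng.normal(1, 1, 20)
        r1, r2 = two_sample_t(a, b), two_sample_t(b, a)
        assert r1.statistic == pytest.approx(-r2.statistic)
        assert r1.p_value == pytest.approx(r2.p_value)

    def test_welch_flag(self, rng):
        a, b = rng.normal(0, 1, 10), rng.normal(0, 5, 40)
        r = two_sample_t(a, b, pooled=False)
        assert r.method == "t_welch"
        assert r.df != pytest.approx(48.0)


class TestSpearman:
    def test_perfect_and_reversed(self):
        x = [1.0, 2, 3, 4, 5]
        assert spearman_corr(x, x).statistic == pytest.approx(1.0)
        assert spearman_corr(x, x[::-1]).statistic == pytest.approx(-1.0)

    def test_textbook_formula(self):
        # 1 - 6*sum(d^2)/(n(n^2-1)) with sum(d^2) = 4, n = 5
        r = spearman_corr([1, 2, 3, 4, 5], [2, 1, 4, 3, 5])
        assert r.statistic == pytest.approx(0.8, abs=1e-12)

    def test_monotone_transform_invariance(self, rng):
        x = rng.normal(size=30)
        y = rng.normal(size=30)
        base = spearman_corr(x, y).statistic
        assert spearman_corr(np.exp(x), y).statistic == pytest.approx(base)
        assert spearman_corr(x, y**3).statistic == pytest.approx(base)

    def test_constant_vector_rejected(self):
        with pytest.raises(DegenerateInputError):
            spearman_corr(np.ones(5), np.arange(5.0))


class TestHierarchicalRegression:
    def test_perfect_step1_fit(self, rng):
        x = rng.normal(size=20)
        hr = hierarchical_regression(2.0 * x + 1.0, x, rng.normal(size=20))
        assert hr.step1_r2 == pytest.approx(1.0)

    def test_df_structure_at_cohort_size(self, rng):
        y = rng.normal(size=43)
        hr = hierarchical_regression(y, rng.normal(size=43), rng.normal(size=43))
        assert hr.step1_df == (1, 41)
        assert hr.f_change_df == (1, 40)

    def test_coefficients_match_normal_equations(self):
        # small printed fixture, solved directly via the normal equations
        y = np.array([2.3, 1.1, 3.7, 2.9, 0.5, 4.2, 3.3, 1.8])
        x1 = np.array([1.0, 0.2, 1.8, 1.4, -0.3, 2.1, 1.6, 0.7])
        x2 = np.array([0.0, 1.0, 0.0, 1.0, 0.0, 1.0, 0.0, 1.0])
        X = np.column_stack([np.ones(8), x1, x2])
        beta = np.linalg.solve(X.T @ X, X.T @ y)
        hr = hierarchical_regression(y, x1, x2)
        got = [hr.coefficients["const"][0], hr.coefficients["x1"][0], hr.coefficients["x2"][0]]
        assert np.allclose(got, beta, atol=1e-10)

    def test_r2_never_decreases(self, rng):
        for _ in range(10):
            y = rng.normal(size=25)
            hr = hierarchical_regression(y, rng.normal(size=25), rng.normal(size=25))
            assert hr.step2_r2 >= hr.step1_r2 - 1e-12

    def test_too_few_observations_rejected(self, rng):
        with pytest.raises(ValueError):
            hierarchical_regression(rng.normal(size=3), rng.normal(size=3), rng.normal(size=3))


class TestMedianSplit:
    def test_even_distinct(self):
        assert median_split([1, 2, 3, 4]).tolist() == ["low", "low", "high", "high"]

    def test_thirteen_distinct_splits_seven_six(self, rng):
        v = rng.permutation(np.arange(13.0) * 1.7 + 0.4)
        labels = median_split(v)
        assert (labels == "low").sum() == 7
        assert (labels == "high").sum() == 6

    def test_all_equal_goes_low(self):
        assert median_split([2.0, 2.0, 2.0]).tolist() == ["low", "low", "low"]


class TestAnovaTukey:
    def test_identical_groups_f_zero(self):
        v = [1.0, 2, 3] * 3
        labels = ["a"] * 3 + ["b"] * 3 + ["c"] * 3
        f, pairs = anova_tukey(v, labels)
        assert f.statistic == pytest.approx(0.0)
        assert all(p["p_adj"] > 0.99 for p in pairs)

    def test_two_groups_f_equals_pooled_t_squared(self, rng):
        a, b = rng.normal(0, 1, 12), rng.normal(1, 1, 9)
        f, _ = anova_tukey(np.concatenate([a, b]), ["a"] * 12 + ["b"] * 9)
        t = two_sample_t(a, b, pooled=True)
        assert f.statistic == pytest.approx(t.statistic**2, abs=1e-9)

    def test_separated_groups_all_significant(self, rng):
        v = np.concatenate([rng.normal(0, 0.1, 8), rng.normal(10, 0.1, 8), rng.normal(20, 0.1, 8)])
        labels = ["a"] * 8 + ["b"] * 8 + ["c"] * 8
        f, pairs = anova_tukey(v, labels)
        assert all(p["p_adj"] < 0.001 for p in pairs)

    def test_df_structure(self, rng):
        v = rng.normal(size=43)
        labels = ["a"] * 7 + ["b"] * 6 + ["c"] * 30
        f, _ = anova_tukey(v, labels)
        assert f.df == (2.0, 40.0)

    def test_degenerate_group_rejected(self):
        with pytest.raises(DegenerateInputError):
            anova_tukey([1.0, 2.0, 3.0], ["a", "a", "b"])
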