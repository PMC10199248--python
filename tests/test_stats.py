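import numpy as np
import pytest
import scipy.stats as sps

from _oracles import icc21_hand, mannwhitney_exact_p, mannwhitney_permutation_p
from dotfrac.stats import (
    StatResult,
    adjusted_group_regression,
    anova_tukey,
    bonferroni_threshold,
    icc,
    mann_whitney,
)


class TestMannWhitney:
    def test_identical_samples_give_p_one(self):
        x = [1.0, 2.0, 3.0, 4.0]
        res = mann_whitney(x, x)
        assert res.statistic == pytest.approx(len(x) ** 2 / 2)
        assert res.p_value == pytest.approx(1.0)

    def test_complete_separation_exact_p(self):
        res = mann_whitney([1, 2, 3], [10, 11, 12])
        assert res.p_value == pytest.approx(0.1, abs=1e-12)
        assert res.p_value == pytest.approx(mannwhitney_exact_p([1, 2, 3], [10, 11, 12]))

    def test_exact_branch_matches_enumeration_oracle(self, rng):
        x = rng.normal(0, 1, 5)
        y = rng.normal(0.8, 1, 6)
        res = mann_whitney(x, y)
        assert res.p_value == pytest.approx(mannwhitney_exact_p(x, y), abs=1e-12)

    def test_tied_data_matches_permutation_oracle(self):
        x = [1.0, 2.0, 2.0, 3.0, 5.0, 5.0, 6.0, 8.0, 8.0, 9.0, 4.0]
        y = [2.0, 2.0, 4.0, 5.0, 5.0, 7.0, 8.0, 8.0, 9.0, 9.0, 11.0]
        res = mann_whitney(x, y)
        p_perm = mannwhitney_permutation_p(x, y, n_perm=100_000, seed=0)
        se = np.sqrt(p_perm * (1 - p_perm) / 100_000)
        assert abs(res.p_value - p_perm) < 4 * se + 1e-3

    def test_invariant_under_monotone_transform(self, rng):
        x = rng.lognormal(0, 0.4, 12)
        y = rng.lognormal(0.3, 0.4, 15)
        res_raw = mann_whitney(x, y)
        res_log = mann_whitney(np.log(x), np.log(y))
        assert res_raw.p_value == pytest.approx(res_log.p_value, rel=1e-12)

    def test_small_samples_rejected(self):
        with pytest.raises(ValueError):
            mann_whitney([1.0], [2.0, 3.0])


class TestICC:
    def test_duplicated_sessions_give_one(self, rng):
        a = rng.normal(0, 1, 8)
        assert icc(np.column_stack([a, a])) == pytest.approx(1.0)

    def test_constant_shift_penalised_below_one(self, rng):
        a = rng.normal(0, 1, 8)
        shifted = icc(np.column_stack([a, a + 1.0]))
        assert shifted < 1.0

    def test_independent_sessions_near_zero(self, rng):
        m = rng.normal(0, 1, size=(200, 2))
        assert abs(icc(m)) < 0.1

    def test_worked_matrix_matches_hand_oracle(self):
        m = np.array([[9.0, 10.0], [6.0, 5.0], [8.0, 8.5], [2.0, 3.0], [7.0, 6.0]])
        assert icc(m) == pytest.approx(icc21_hand(m), rel=1e-12)

    def test_matches_pingouin_two_way_random_single(self):
        pingouin = pytest.importorskip("pingouin")
        import pandas as pd
        m = np.array([[9.0, 10.0], [6.0, 5.0], [8.0, 8.5], [2.0, 3.0], [7.0, 6.0]])
        long = pd.DataFrame({
            "subject": np.repeat(np.arange(5), 2),
            "session": np.tile(np.arange(2), 5),
            "value": m.ravel(),
        })
        table = pingouin.intraclass_corr(long, targets="subject", raters="session",
                                         ratings="value").set_index("Type")
        # two-way random, absolute agreement, single rater: labelled ICC2
        # or ICC(A,1) depending on the pingouin release
        key = "ICC2" if "ICC2" in table.index else "ICC(A,1)"
        assert icc(m) == pytest.approx(float(table.loc[key, "ICC"]), abs=1e-9)

    def test_missing_cells_rejected(self):
        m = np.array([[1.0, 2.0], [np.nan, 3.0]])
        with pytest.raises(ValueError, match="missing"):
            icc(m)

    def test_too_small_matrix_rejected(self):
        with pytest.raises(ValueError):
            icc(np.array([[1.0, 2.0]]))


class TestAnovaTukey:
    def test_identical_groups_f_zero_p_one(self):
        g = [1.0, 2.0, 3.0]
        omnibus = anova_tukey([g, g, g])[0]
        assert omnibus.statistic == pytest.approx(0.0, abs=1e-12)
        assert omnibus.p_value == pytest.approx(1.0)

    def test_one_shifted_group_dominates_pairwise(self):
        base = [0.0, 0.01, -0.01, 0.005]
        shifted = [5.0, 5.01, 4.99, 5.005]
        results = anova_tukey([base, base, shifted], labels=["a", "b", "c"],
                              alpha_adj=0.003)
        omnibus, ab, ac, bc = results
        assert omnibus.p_value < 1e-6
        assert ac.p_value < 0.003 and bc.p_value < 0.003
        assert ab.p_value > 0.5
        assert ac.significant and not ab.significant

    def test_two_groups_reduce_to_pooled_t_test(self, rng):
        x = rng.normal(0, 1, 10)
        y = rng.normal(0.5, 1, 12)
        omnibus = anova_tukey([x, y])[0]
        t = sps.ttest_ind(x, y)
        assert omnibus.statistic == pytest.approx(t.statistic**2, rel=1e-10)
        assert omnibus.p_value == pytest.approx(t.pvalue, rel=1e-10)

    def test_tukey_never_anticonservative_vs_pooled_t_test(self, rng):
        # the comparable unadjusted test uses the same pooled error variance
        # and residual degrees of freedom as the HSD procedure
        for _ in range(20):
            groups = [rng.normal(rng.normal(0, 0.5), 1, rng.integers(4, 9))
                      for _ in range(3)]
            sizes = [len(g) for g in groups]
            df = sum(sizes) - len(groups)
            mse = sum((len(g) - 1) * np.var(g, ddof=1) for g in groups) / df
            results = anova_tukey(groups)
            for res in results[1:]:
                i, j = (int(g[-1]) - 1 for g in res.groups)
                t = (np.mean(groups[i]) - np.mean(groups[j])) / np.sqrt(
                    mse * (1 / sizes[i] + 1 / sizes[j])
                )
                raw = 2 * sps.t.sf(abs(t), df)
                assert res.p_value >= raw - 1e-12

    def test_undersized_group_rejected(self):
        with pytest.raises(ValueError):
            anova_tukey([[1.0, 2.0], [3.0]])


class TestAdjustedRegression:
    def test_exact_noiseless_coefficients(self):
        cov = np.array([1.0, 2.0, 3.0, 4.0, 5.0, 6.0])
        group = np.array(["ctrl", "ctrl", "ctrl", "pat", "pat", "pat"])
        outcome = 1.0 + 2.0 * cov + 3.0 * (group == "pat")
        res = adjusted_group_regression(outcome, group, cov)[0]
        assert res.effect == pytest.approx(3.0, rel=1e-10)
        assert res.groups == ("pat", "ctrl")

    def test_outcome_fully_explained_by_covariate(self, rng):
        cov = rng.normal(100, 15, 60)
        group = np.array(["a", "b"] * 30)
        res = adjusted_group_regression(cov.copy(), group, cov)[0]
        assert res.effect == pytest.approx(0.0, abs=1e-9)

    def test_uncorrelated_covariate_leaves_group_difference(self, rng):
        n = 4000
        group = np.array(["ctrl"] * n + ["pat"] * n)
        outcome = np.concatenate([rng.normal(0, 1, n), rng.normal(0.7, 1, n)])
        cov = rng.normal(50, 5, 2 * n)
        res = adjusted_group_regression(outcome, group, cov)[0]
        unadjusted = outcome[n:].mean() - outcome[:n].mean()
        assert res.effect == pytest.approx(unadjusted, abs=0.05)

    def test_reference_group_selection(self, rng):
        outcome = rng.normal(0, 1, 12)
        group = np.array(["b", "a", "c"] * 4)
        results = adjusted_group_regression(outcome, group, rng.normal(0, 1, 12),
                                            reference="b")
        assert {r.groups[0] for r in results} == {"a", "c"}

    def test_constant_covariate_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            adjusted_group_regression([1.0, 2.0, 3.0, 4.0],
                                      ["a", "a", "b", "b"], [5.0] * 4)


class TestBonferroni:
    def test_single_comparison_unchanged(self):
        assert bonferroni_threshold(0.05, 1) == 0.05

    def test_fifteen_comparisons_match_printed_threshold(self):
        # 0.05 / 15 = 0.00333..., reported operationally as "< 0.003"
        adj = bonferroni_threshold(0.05, 15)
        assert adj == pytest.approx(1 / 300)
        assert 0.003 < adj < 0.0034

    def test_invalid_m_rejected(self):
        with pytest.raises(ValueError):
            bonferroni_threshold(0.05, 0)

    def test_result_significance_uses_adjusted_threshold(self):
        res = StatResult("demo", 1.0, 0.004, bonferroni_threshold(0.05, 15),
                         ("a", "b"), (5, 5))
        assert not res.significant
        assert StatResult("demo", 1.0, 0.002, res.alpha_adj, ("a", "b"), (5, 5)).significant

    def test_p_value_range_enforced(self):
        with pytest.raises(ValueError):
            StatResult("demo", 0.0, 1.5, 0.05, ("a", "b"), (2, 2))


class TestTypeIError:
    def test_rejection_rate_nominal_under_null(self, rng):
        # identical lognormal populations, alpha = 0.05: the rejection rate
        # over many replicates must sit near the nominal level
        rejections = 0
        n_rep = 1200
        for _ in range(n_rep):
            x = rng.lognormal(np.log(0.6), 0.07, 20)
            y = rng.lognormal(np.log(0.6), 0.07, 20)
            if mann_whitney(x, y).p_value < 0.05:
                rejections += 1
        assert 0.03 <= rejections / n_rep <= 0.07

    def test_cohort_generator_null_is_calibrated(self):
        # two groups with identical targets: Mann-Whitney on per-subject
        # grey-matter medians of the generated truth maps rejects at the
        # nominal 5% rate
        from dotfrac.scheme import build_scheme
        from dotfrac.synthetic import CohortSpec, GroupSpec, default_phantom, generate_cohort

        template = default_phantom(shape=10, sigma=0.0, seed=0)
        scheme = build_scheme(order_seed=1)
        gm = (template.labels >= 1) & (template.labels <= 10)
        groups = (GroupSpec("g1", 15), GroupSpec("g2", 15))
        rejections = 0
        n_rep = 1000
        for rep in range(n_rep):
            records = generate_cohort(CohortSpec(groups, template, seed=rep),
                                      scheme, with_signal=False)
            a = [float(np.median(r.truth.md[gm])) for r in records if r.group == "g1"]
            b = [float(np.median(r.truth.md[gm])) for r in records if r.group == "g2"]
            if mann_whitney(a, b).p_value < 0.05:
                rejections += 1
        assert 0.03 <= rejections / n_rep <= 0.07
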