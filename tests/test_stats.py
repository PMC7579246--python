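"""Statistical layer: tables, ANOVA/ANCOVA, regressions, alpha adjustment."""

import numpy as np
import pandas as pd
import pytest

from gwmci.stats import (
    CollinearityError,
    ContingencyTable,
    DegenerateDataError,
    ancova_group_test,
    anova_from_summary,
    average_intercorrelation,
    chi_square,
    contingency,
    effective_alpha,
    hierarchical_regression,
    one_way_anova,
    planned_contrasts,
    standardize_and_fit,
    stepwise_regression,
)


def _ptsd_table():
    yes = np.array([10, 12, 6])
    sizes = np.array([25, 98, 79])
    return ContingencyTable(("yes", "no"), ("MCI", "INT", "CN"),
                            np.vstack([yes, sizes - yes]))


class TestContingency:
    def test_crosstab_counts(self):
        labels = ["MCI"] * 25 + ["INT"] * 98 + ["CN"] * 79
        ptsd = ([1] * 10 + [0] * 15) + ([1] * 12 + [0] * 86) + ([1] * 6 + [0] * 73)
        tab = contingency(labels, ptsd)
        frame = tab.to_frame()
        assert list(frame.loc["1", ["MCI", "INT", "CN"]]) == [10, 12, 6]
        assert tab.total == 202

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            contingency([], [])

    def test_degenerate_single_category_rejected(self):
        with pytest.raises(ValueError, match="2x2"):
            contingency(["a", "a", "b"], [1, 1, 1])

    def test_single_subject_rejected(self):
        with pytest.raises(ValueError):
            contingency(["a"], [1])


class TestChiSquare:
    def test_ptsd_table_statistic(self):
        res = chi_square(_ptsd_table())
        assert res.statistic == pytest.approx(17.12, abs=0.005)
        assert res.df == 2

    def test_expected_margins_match_observed(self):
        res = chi_square(_ptsd_table())
        obs = _ptsd_table().counts
        assert res.expected.sum(axis=0) == pytest.approx(obs.sum(axis=0))
        assert res.expected.sum(axis=1) == pytest.approx(obs.sum(axis=1))

    def test_proportional_rows_give_zero(self):
        tab = ContingencyTable(("a", "b"), ("x", "y", "z"),
                               np.array([[10, 20, 30], [20, 40, 60]]))
        assert chi_square(tab).statistic == pytest.approx(0.0, abs=1e-12)

    def test_permutation_and_transpose_invariance(self, rng):
        counts = rng.integers(1, 40, size=(3, 4))
        base = chi_square(ContingencyTable(("a", "b", "c"), ("w", "x", "y", "z"), counts)).statistic
        perm = counts[[2, 0, 1]][:, [3, 1, 0, 2]]
        assert chi_square(ContingencyTable(("a", "b", "c"), ("w", "x", "y", "z"), perm)
                          ).statistic == pytest.approx(base)
        assert chi_square(ContingencyTable(("w", "x", "y", "z"), ("a", "b", "c"), counts.T)
                          ).statistic == pytest.approx(base)

    def test_zero_margin_rejected(self):
        tab = ContingencyTable(("a", "b"), ("x", "y"), np.array([[0, 0], [3, 4]]))
        with pytest.raises(DegenerateDataError, match="margin"):
            chi_square(tab)


class TestAnova:
    def test_two_group_hand_decomposition(self):
        # groups (1,2,3) and (4,5,6): SSB = 13.5, MSW = 1 -> F = 13.5
        res = one_way_anova([1, 2, 3, 4, 5, 6], ["a"] * 3 + ["b"] * 3)
        assert res.F == pytest.approx(13.5)
        assert (res.df_between, res.df_within) == (1, 4)

    def test_equal_means_zero_f(self):
        res = one_way_anova([1, 2, 3, 1, 2, 3], ["a"] * 3 + ["b"] * 3)
        assert res.F == pytest.approx(0.0, abs=1e-12)

    def test_constant_values_degenerate(self):
        with pytest.raises(DegenerateDataError):
            one_way_anova([5, 5, 5, 5], ["a", "a", "b", "b"])

    def test_singleton_group_rejected(self):
        with pytest.raises(DegenerateDataError, match="singleton"):
            one_way_anova([1, 2, 3], ["a", "a", "b"])

    def test_summary_identity_with_raw(self, rng):
        values = rng.normal(size=30)
        labels = np.repeat(["a", "b", "c"], 10)
        df = pd.DataFrame({"y": values, "g": labels})
        means = df.groupby("g")["y"].mean()
        sds = df.groupby("g")["y"].std(ddof=1)
        ns = df.groupby("g")["y"].size()
        raw = one_way_anova(values, labels)
        summ = anova_from_summary(means, sds, ns)
        assert summ.F == pytest.approx(raw.F, abs=1e-9)
        assert (summ.df_between, summ.df_within) == (raw.df_between, raw.df_within)

    def test_summary_equal_means(self):
        res = anova_from_summary([5, 5, 5], [1, 2, 3], [10, 10, 10])
        assert res.F == pytest.approx(0.0, abs=1e-12)

    def test_group_age_summaries(self):
        # recomputing the emulated study's age comparison from its printed
        # group summaries: 51.8±6.7 (25), 53.7±7.3 (98), 55.4±8.4 (79)
        res = anova_from_summary([51.8, 53.7, 55.4], [6.7, 7.3, 8.4], [25, 98, 79])
        assert res.F == pytest.approx(2.38, abs=0.005)


class TestAncovaAndContrasts:
    def test_no_covariates_matches_anova(self, rng):
        y = rng.normal(size=40)
        g = np.repeat(["MCI", "INT", "CN"], [10, 15, 15])
        plain = one_way_anova(y, g)
        adj, _ = ancova_group_test(y, g, None, reference="CN")
        assert adj.F == pytest.approx(plain.F, abs=1e-9)
        assert (adj.df_between, adj.df_within) == (plain.df_between, plain.df_within)

    def test_outcome_equal_to_covariate_kills_group(self, rng):
        x = rng.normal(size=30)
        g = np.repeat(["A", "B", "C"], 10)
        adj, _ = ancova_group_test(x, g, {"x": x}, reference="A")
        assert adj.F == pytest.approx(0.0, abs=1e-9)

    def test_collinear_design_rejected(self, rng):
        y = rng.normal(size=30)
        g = np.repeat(["A", "B", "C"], 10)
        x = rng.normal(size=30)
        with pytest.raises(CollinearityError, match="x2"):
            ancova_group_test(y, g, {"x1": x, "x2": 2 * x}, reference="A")

    def test_self_contrast_is_null(self, rng):
        y = rng.normal(size=30)
        g = np.repeat(["A", "B", "C"], 10)
        _, fit = ancova_group_test(y, g, None, reference="A")
        (c,) = planned_contrasts(fit, [("B", "B")])
        assert c.estimate == 0.0 and c.p == 1.0

    def test_unadjusted_contrast_equals_mean_difference(self, rng):
        y = rng.normal(size=30)
        g = np.repeat(["A", "B", "C"], 10)
        _, fit = ancova_group_test(y, g, None, reference="A")
        (c,) = planned_contrasts(fit, [("B", "C")])
        expected = y[10:20].mean() - y[20:].mean()
        assert c.estimate == pytest.approx(expected, abs=1e-10)

    def test_unknown_pair_rejected(self, rng):
        y = rng.normal(size=30)
        g = np.repeat(["A", "B", "C"], 10)
        _, fit = ancova_group_test(y, g, None, reference="A")
        with pytest.raises(ValueError, match="'D'"):
            planned_contrasts(fit, [("D", "A")])


class TestStandardizeAndFit:
    def test_outcome_identical_to_term(self, rng):
        x = rng.normal(size=20)
        fit = standardize_and_fit(x, {"x": x})
        assert fit.std_beta["x"] == pytest.approx(1.0)
        assert fit.r2 == pytest.approx(1.0)

    def test_orthogonal_term_zero_beta(self, rng):
        x = rng.normal(size=50)
        y = rng.normal(size=50)
        y = y - y.mean()
        x = x - x.mean()
        y_orth = y - (y @ x) / (x @ x) * x  # outcome orthogonal to x
        fit = standardize_and_fit(y_orth, {"x": x})
        assert fit.std_beta["x"] == pytest.approx(0.0, abs=1e-10)

    def test_matches_normal_equations_on_crafted_design(self):
        x1 = np.array([1, 2, 3, 4, 5, 6, 7, 8, 9, 10], dtype=float)
        x2 = np.array([2, 1, 4, 3, 6, 5, 8, 7, 10, 9], dtype=float)
        y = 1.5 + 2.0 * x1 - 0.5 * x2 + np.array(
            [0.1, -0.2, 0.05, 0.3, -0.1, 0.0, 0.2, -0.3, 0.15, -0.05]
        )
        X = np.column_stack([np.ones(10), x1, x2])
        beta = np.linalg.solve(X.T @ X, X.T @ y)
        fit = standardize_and_fit(y, {"x1": x1, "x2": x2})
        assert fit.coefficients["const"] == pytest.approx(beta[0], abs=1e-10)
        assert fit.coefficients["x1"] == pytest.approx(beta[1], abs=1e-10)
        assert fit.coefficients["x2"] == pytest.approx(beta[2], abs=1e-10)

    def test_zero_variance_term_rejected(self, rng):
        with pytest.raises(DegenerateDataError, match="'c'"):
            standardize_and_fit(rng.normal(size=10), {"c": np.ones(10)})

    def test_residual_df_accounting(self, rng):
        fit = standardize_and_fit(rng.normal(size=25),
                                  {"a": rng.normal(size=25), "b": rng.normal(size=25)})
        assert fit.n == 25 and fit.residual_df == 25 - 3


class TestHierarchicalRegression:
    def test_single_block_equals_plain_fit(self, rng):
        y = rng.normal(size=40)
        data = {"a": rng.normal(size=40), "b": rng.normal(size=40)}
        steps = hierarchical_regression(y, [["a", "b"]], data)
        direct = standardize_and_fit(y, data)
        assert len(steps) == 1
        assert steps[0].fit.r2 == pytest.approx(direct.r2)
        assert steps[0].fit.coefficients == pytest.approx(direct.coefficients)

    def test_r2_nondecreasing_and_final_equals_full(self, rng):
        n = 60
        data = {k: rng.normal(size=n) for k in "abcd"}
        y = data["a"] + 0.5 * data["c"] + rng.normal(size=n)
        steps = hierarchical_regression(y, [["a", "b"], ["c"], ["d"]], data)
        r2s = [s.fit.r2 for s in steps]
        assert all(b >= a - 1e-12 for a, b in zip(r2s, r2s[1:]))
        full = standardize_and_fit(y, pd.DataFrame(data)[["a", "b", "c", "d"]])
        assert steps[-1].fit.r2 == pytest.approx(full.r2)
        assert sum(s.delta_r2 for s in steps) == pytest.approx(full.r2, abs=1e-10)

    def test_irrelevant_second_block_adds_nothing(self, rng):
        n = 80
        a = rng.normal(size=n)
        y = 2 * a + rng.normal(size=n)
        resid = y - np.polyval(np.polyfit(a, y, 1), a)
        # d is orthogonalized against both the outcome residual and block 1
        d = rng.normal(size=n)
        for v in (a - a.mean(), resid):
            d = d - (d @ v) / (v @ v) * v
        steps = hierarchical_regression(y, [["a"], ["d"]], {"a": a, "d": d})
        assert steps[1].delta_r2 == pytest.approx(0.0, abs=1e-10)

    def test_rank_deficient_step_named(self, rng):
        a = rng.normal(size=30)
        with pytest.raises(CollinearityError, match="step 2"):
            hierarchical_regression(rng.normal(size=30), [["a"], ["b"]],
                                    {"a": a, "b": a * 3})


class TestStepwiseRegression:
    def test_single_strong_candidate_enters(self, rng):
        x = rng.normal(size=100)
        y = x + 0.1 * rng.normal(size=100)
        fit, order = stepwise_regression(y, ["x"], {"x": x})
        assert order == ["x"] and fit.terms == ("x",)

    def test_pure_noise_yields_empty_model(self, rng):
        n = 100
        y = rng.normal(size=n)
        data = {}
        for name in ("a", "b", "c"):
            v = rng.normal(size=n)
            yc = y - y.mean()
            v = v - (v @ yc) / (yc @ yc) * yc  # orthogonal to outcome
            data[name] = v
        fit, order = stepwise_regression(y, list(data), data)
        assert fit is None and order == []

    def test_recovers_planted_signals(self, rng):
        """Strong and medium predictors enter; the null one stays out."""
        n, reps = 200, 200
        hits = 0
        for _ in range(reps):
            strong = rng.normal(size=n)
            medium = rng.normal(size=n)
            null = rng.normal(size=n)
            y = 0.5 * strong + 0.25 * medium + rng.normal(size=n)
            fit, order = stepwise_regression(
                y, ["strong", "medium", "null"],
                {"strong": strong, "medium": medium, "null": null},
            )
            if fit is not None and set(fit.terms) == {"strong", "medium"}:
                hits += 1
        assert hits / reps >= 0.90

    def test_invalid_thresholds_rejected(self, rng):
        with pytest.raises(ValueError, match="p_enter"):
            stepwise_regression(rng.normal(size=10), ["x"],
                                {"x": rng.normal(size=10)},
                                p_enter=0.2, p_remove=0.1)


class TestAverageIntercorrelation:
    def test_duplicated_columns(self, rng):
        x = rng.normal(size=30)
        assert average_intercorrelation({"a": x, "b": x}) == pytest.approx(1.0)

    def test_orthogonal_columns(self, rng):
        a = rng.normal(size=50)
        b = rng.normal(size=50)
        a = a - a.mean()
        b = b - b.mean()
        b = b - (b @ a) / (a @ a) * a
        assert average_intercorrelation({"a": a, "b": b}) == pytest.approx(0.0, abs=1e-10)

    def test_constructed_pairwise_correlations(self, rng):
        # build 3 columns whose sample correlations are exactly (0.5, 0.6, 0.7)
        target = np.array([[1.0, 0.5, 0.6], [0.5, 1.0, 0.7], [0.6, 0.7, 1.0]])
        q, _ = np.linalg.qr(rng.normal(size=(40, 3)) - rng.normal(size=(1, 3)))
        q = q - q.mean(axis=0)
        q, _ = np.linalg.qr(q)  # orthonormal, mean-adjusted
        X = q @ np.linalg.cholesky(target).T
        assert average_intercorrelation(X) == pytest.approx(0.6, abs=1e-9)

    def test_zero_variance_column_rejected(self, rng):
        with pytest.raises(DegenerateDataError):
            average_intercorrelation({"a": rng.normal(size=10), "b": np.ones(10)})


class TestEffectiveAlpha:
    def test_printed_thresholds(self):
        assert effective_alpha(5, 0.58).rounded(2) == 0.03
        assert effective_alpha(15, 0.21).rounded(3) == 0.006

    def test_fully_dependent_limit(self):
        adj = effective_alpha(7, 1.0, alpha_family=0.05)
        assert adj.m_eff == pytest.approx(1.0)
        assert adj.alpha_adj == pytest.approx(0.05)

    def test_independent_limit_is_sidak(self):
        adj = effective_alpha(10, 0.0, alpha_family=0.05)
        assert adj.alpha_adj == pytest.approx(1 - 0.95 ** (1 / 10))

    def test_negative_rbar_clamped(self, caplog):
        adj = effective_alpha(5, -0.2)
        assert adj.r_bar == 0.0

    def test_monotone_and_bounded(self):
        alphas_r = [effective_alpha(8, r).alpha_adj for r in np.linspace(0, 1, 11)]
        assert all(b >= a for a, b in zip(alphas_r, alphas_r[1:]))
        alphas_n = [effective_alpha(n, 0.4).alpha_adj for n in range(1, 20)]
        assert all(b <= a for a, b in zip(alphas_n, alphas_n[1:]))
        for n in (2, 5, 15):
            for r in (0.0, 0.3, 0.9):
                a = effective_alpha(n, r).alpha_adj
                assert 0.05 / n - 1e-12 <= a <= 0.05 + 1e-12

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ValueError):
            effective_alpha(0, 0.5)
        with pytest.raises(ValueError):
            effective_alpha(5, 1.2)
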