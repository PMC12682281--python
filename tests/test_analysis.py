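"""Exclusions, bias statistic, group tests, correlation, ridge inference."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from scalegeom import presets
from scalegeom.analysis import (
    IC_PREDICTORS,
    apply_exclusions,
    compute_bias,
    evenness_correlation,
    group_tests,
    independent_t,
    mixed_anova,
    one_sample_t,
    paired_t,
    ridge_interval_regression,
    set_score_table,
)
from scalegeom.settheory import enumerate_set_classes
from scalegeom.simulate import ResponseModel, simulate_cohort
from scalegeom.presets import preset_cohort_design


def make_table(rows):
    """rows: (participant, set, choice*counts, comprehension)"""
    out = []
    trial = 0
    for pid, sid, n_note, n_contour, n_nodiff, comp in rows:
        for choice, n in [
            ("note", n_note), ("contour", n_contour), ("no_difference", n_nodiff)
        ]:
            for _ in range(n):
                out.append(
                    {
                        "participant_id": pid,
                        "set_id": sid,
                        "block": 0,
                        "trial": trial,
                        "choice": choice,
                        "comprehension_rating": comp,
                        "years_training": 0,
                        "plays_instrument": False,
                    }
                )
                trial += 1
    return pd.DataFrame(out)


class TestExclusions:
    def test_retained(self):
        table = make_table([(1, "A", 12, 8, 0, 4)])
        kept, log = apply_exclusions(table)
        assert len(kept) == 20 and len(log) == 0

    def test_comprehension_boundary(self):
        table = make_table([(1, "A", 12, 8, 0, 3), (2, "A", 12, 8, 0, 4)])
        kept, log = apply_exclusions(table)
        assert kept["participant_id"].unique().tolist() == [2]
        assert log.iloc[0]["reason"] == "low_comprehension"

    def test_fourteen_usable_dropped(self):
        table = make_table(
            [(1, "A", 8, 6, 6, 5), (1, "B", 10, 10, 0, 5)]
        )
        kept, log = apply_exclusions(table, min_responses=15)
        assert set(kept["set_id"]) == {"B"}
        assert log.iloc[0]["detail"] == 14

    def test_missing_columns(self):
        with pytest.raises(ValueError, match="lacks columns"):
            apply_exclusions(pd.DataFrame({"choice": []}))


class TestBias:
    def test_arithmetic(self):
        bias = compute_bias(make_table([(1, "A", 30, 20, 0, 5)]))
        assert bias.iloc[0]["bias"] == pytest.approx(0.2)

    def test_symmetry(self):
        bias = compute_bias(make_table([(1, "A", 15, 15, 0, 5)]))
        assert bias.iloc[0]["bias"] == 0.0

    def test_boundary(self):
        bias = compute_bias(make_table([(1, "A", 20, 0, 0, 5)]))
        assert bias.iloc[0]["bias"] == 1.0

    def test_no_difference_excluded_from_denominator(self):
        with_nd = compute_bias(make_table([(1, "A", 30, 20, 17, 5)]))
        without = compute_bias(make_table([(1, "A", 30, 20, 0, 5)]))
        assert with_nd.iloc[0]["bias"] == without.iloc[0]["bias"]

    def test_zero_usable_flagged(self):
        bias = compute_bias(make_table([(1, "A", 0, 0, 20, 5)]))
        assert not bias.iloc[0]["valid"]
        assert np.isnan(bias.iloc[0]["bias"])

    def test_antisymmetric_under_relabeling(self):
        table = make_table([(1, "A", 30, 10, 5, 5), (2, "A", 7, 13, 0, 5)])
        swapped = table.copy()
        swapped["choice"] = swapped["choice"].map(
            {"note": "contour", "contour": "note", "no_difference": "no_difference"}
        )
        a = compute_bias(table)["bias"].to_numpy()
        b = compute_bias(swapped)["bias"].to_numpy()
        np.testing.assert_allclose(a, -b)


class TestGroupTests:
    def test_one_sample_matches_scipy(self, rng):
        x = rng.normal(0.3, 1.0, 30)
        res = one_sample_t(x)
        t, p = stats.ttest_1samp(x, 0)
        assert res.statistic == pytest.approx(t)
        assert res.p_value == pytest.approx(p)
        assert res.df == 29
        assert res.effect_size == pytest.approx(x.mean() / x.std(ddof=1))

    def test_zero_mean_zero_t(self):
        x = np.array([-1.0, 1.0, -2.0, 2.0])
        res = one_sample_t(x)
        assert res.statistic == 0 and res.p_value == pytest.approx(1.0)

    def test_constant_sample_errors(self):
        with pytest.raises(ValueError, match="zero variance"):
            one_sample_t([0.5, 0.5, 0.5])

    def test_paired(self, rng):
        x, y = rng.normal(size=(2, 25))
        res = paired_t(x, y)
        t, p = stats.ttest_rel(x, y)
        assert res.statistic == pytest.approx(t)
        d = (x - y).mean() / (x - y).std(ddof=1)
        assert res.effect_size == pytest.approx(d)

    def test_independent_welch_df(self, rng):
        x = rng.normal(0, 1, 20)
        y = rng.normal(0, 3, 35)
        res = independent_t(x, y)
        t, p = stats.ttest_ind(x, y, equal_var=False)
        assert res.statistic == pytest.approx(t)
        assert res.p_value == pytest.approx(p)
        assert res.df < 53  # Welch df < n1 + n2 - 2 under unequal variance

    def test_mixed_anova_against_ss_oracle(self):
        # balanced toy design: between groups g1/g2/g3 (n=4 subjects each),
        # within levels w1/w2; textbook sums-of-squares decomposition
        rng = np.random.default_rng(8)
        rows = []
        sid = 0
        for g, shift in [("g1", 0.0), ("g2", 0.5), ("g3", 1.0)]:
            for _ in range(4):
                base = rng.normal()
                for w, wshift in [("w1", 0.0), ("w2", 0.8)]:
                    rows.append(
                        {
                            "participant_id": sid,
                            "group": g,
                            "level": w,
                            "y": base + shift + wshift + rng.normal(0, 0.3),
                        }
                    )
                sid += 1
        df = pd.DataFrame(rows)

        # oracle: explicit SS decomposition for a balanced mixed design
        a, b, n = 3, 2, 4
        grand = df["y"].mean()
        gm = df.groupby("group")["y"].mean()
        wm = df.groupby("level")["y"].mean()
        cm = df.groupby(["group", "level"])["y"].mean()
        sm = df.groupby("participant_id")["y"].mean()
        subj_group = df.groupby("participant_id")["group"].first()
        ss_a = b * n * ((gm - grand) ** 2).sum()
        ss_subj = b * sum(
            (sm[s] - gm[subj_group[s]]) ** 2 for s in sm.index
        )
        ss_b = a * n * ((wm - grand) ** 2).sum()
        ss_ab = n * sum(
            (cm[(g, w)] - gm[g] - wm[w] + grand) ** 2
            for g in gm.index for w in wm.index
        )
        ss_err = sum(
            (r["y"] - cm[(r["group"], r["level"])] - sm[r["participant_id"]]
             + gm[r["group"]]) ** 2
            for _, r in df.iterrows()
        )
        f_a = (ss_a / (a - 1)) / (ss_subj / (a * (n - 1)))
        f_b = (ss_b / (b - 1)) / (ss_err / (a * (n - 1) * (b - 1)))
        f_ab = (ss_ab / ((a - 1) * (b - 1))) / (ss_err / (a * (n - 1) * (b - 1)))

        aov = mixed_anova(
            df, dv="y", within="level", between="group", subject="participant_id"
        ).set_index("source")
        assert aov.loc["group", "F"] == pytest.approx(f_a, rel=1e-6)
        assert aov.loc["level", "F"] == pytest.approx(f_b, rel=1e-6)
        assert aov.loc["Interaction", "F"] == pytest.approx(f_ab, rel=1e-6)
        assert aov.loc["group", "eta_p2"] == pytest.approx(
            ss_a / (ss_a + ss_subj), rel=1e-6
        )
        assert aov.loc["level", "eta_p2"] == pytest.approx(
            ss_b / (ss_b + ss_err), rel=1e-6
        )

    def test_group_tests_report(self):
        design = preset_cohort_design("exp3")
        table = simulate_cohort(
            ResponseModel(intercept=0.5, sigma_u=0.2), design, 40, seed=9
        )
        bias = compute_bias(table)
        report = group_tests(bias)
        comparisons = set(report["comparison"])
        assert "0369 vs 0" in comparisons
        assert any("vs" in c and "0 " not in c for c in comparisons)
        assert (report["p_value"] <= 1).all()


class TestEvennessCorrelation:
    def test_exact_linear(self, classes_12_5):
        scores = set_score_table(
            compute_bias(make_table([(1, "01234", 10, 10, 0, 5)])), classes_12_5
        )
        scores["mean_bias"] = 0.1 + 0.5 * scores["evenness"]
        r, p = evenness_correlation(scores)
        assert r == pytest.approx(1.0)

    def test_zero_variance_errors(self, classes_12_5):
        scores = set_score_table(
            compute_bias(make_table([(1, "01234", 10, 10, 0, 5)])), classes_12_5
        )
        scores["mean_bias"] = 0.5
        with pytest.raises(ValueError):
            evenness_correlation(scores)

    def test_needs_three_sets(self, classes_12_5):
        scores = set_score_table(
            compute_bias(make_table([(1, "01234", 10, 10, 0, 5)])), classes_12_5
        ).head(2)
        scores["mean_bias"] = [0.1, 0.2]
        with pytest.raises(ValueError):
            evenness_correlation(scores)


def toy_scores(rng, n=40, p=3):
    """Full-rank toy design with known linear response."""
    X = rng.normal(size=(n, p))
    beta = np.array([0.5, -0.3, 0.2])
    y = 1.0 + X @ beta + rng.normal(0, 0.01, n)
    cols = {f"ic{i+1}": X[:, i] for i in range(p)}
    return pd.DataFrame({"mean_bias": y, **cols}), beta


class TestRidgeRegression:
    def test_penalty_zero_matches_ols(self, rng):
        scores, beta = toy_scores(rng)
        preds = ("ic1", "ic2", "ic3")
        res = ridge_interval_regression(
            scores, penalty=1e-10, n_perm=100, seed=0, predictors=preds
        )
        X = scores[list(preds)].to_numpy()
        A = np.column_stack([np.ones(len(X)), X])
        ols = np.linalg.lstsq(A, scores["mean_bias"].to_numpy(), rcond=None)[0]
        np.testing.assert_allclose(res.coefficients, ols[1:], atol=1e-8)
        np.testing.assert_allclose(res.intercept, ols[0], atol=1e-8)
        np.testing.assert_allclose(res.coefficients, beta, atol=0.02)

    def test_closed_form_matches_sklearn_at_penalty_one(self, classes_12_5, rng):
        # permutation machinery uses the closed-form ridge map; it must agree
        # with the sklearn point fit it accompanies
        from scalegeom.analysis import _ridge_coef_matrix

        scores = set_score_table(
            compute_bias(make_table([(1, "01234", 10, 10, 0, 5)])), classes_12_5
        )
        y = rng.normal(size=66)
        scores["mean_bias"] = y
        res = ridge_interval_regression(scores, penalty=1.0, n_perm=100, seed=0)
        X = scores[list(IC_PREDICTORS)].to_numpy()
        Xc = X - X.mean(axis=0)
        closed = _ridge_coef_matrix(Xc, 1.0) @ (y - y.mean())
        np.testing.assert_allclose(res.coefficients, closed, atol=1e-10)

    def test_shift_invariance(self, classes_12_5, rng):
        scores = set_score_table(
            compute_bias(make_table([(1, "01234", 10, 10, 0, 5)])), classes_12_5
        )
        scores["mean_bias"] = rng.normal(size=66)
        a = ridge_interval_regression(scores, n_perm=500, seed=3)
        shifted = scores.copy()
        shifted["mean_bias"] = shifted["mean_bias"] + 5.0
        b = ridge_interval_regression(shifted, n_perm=500, seed=3)
        assert a.r == pytest.approx(b.r)
        assert a.model_p == b.model_p
        np.testing.assert_allclose(a.coef_p, b.coef_p)

    def test_ci_contains_point_estimate(self, classes_12_5, rng):
        scores = set_score_table(
            compute_bias(make_table([(1, "01234", 10, 10, 0, 5)])), classes_12_5
        )
        scores["mean_bias"] = rng.normal(size=66)
        res = ridge_interval_regression(scores, n_perm=500, seed=4)
        assert (res.ci_low <= res.coefficients).all()
        assert (res.coefficients <= res.ci_high).all()
        assert ((0 < res.coef_p) & (res.coef_p <= 1)).all()

    def test_deterministic_under_seed(self, classes_12_5, rng):
        scores = set_score_table(
            compute_bias(make_table([(1, "01234", 10, 10, 0, 5)])), classes_12_5
        )
        scores["mean_bias"] = rng.normal(size=66)
        a = ridge_interval_regression(scores, n_perm=300, seed=11)
        b = ridge_interval_regression(scores, n_perm=300, seed=11)
        assert a.model_p == b.model_p
        np.testing.assert_array_equal(a.coef_p, b.coef_p)

    def test_too_few_sets(self, rng):
        scores, _ = toy_scores(rng, n=3, p=3)
        with pytest.raises(ValueError, match="more sets"):
            ridge_interval_regression(
                scores, predictors=("ic1", "ic2", "ic3"), n_perm=100, seed=0
            )

    def test_low_n_perm_warns(self, rng):
        scores, _ = toy_scores(rng)
        with pytest.warns(UserWarning, match="n_perm"):
            ridge_interval_regression(
                scores, predictors=("ic1", "ic2", "ic3"), n_perm=50, seed=0
            )

    def test_loo_extra(self, rng):
        scores, _ = toy_scores(rng)
        res = ridge_interval_regression(
            scores, predictors=("ic1", "ic2", "ic3"), n_perm=100, seed=0,
            include_loo=True,
        )
        assert res.loo_r is not None and -1 <= res.loo_r <= 1
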