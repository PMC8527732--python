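import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm
from scipy import stats

from retinaquant.cohort_stats import (
    adjusted_group_compare,
    fit_clustered_lm,
    group_compare,
    interaction_model,
    multivariate_model,
    roc_cutoff,
    univariate_screen,
)
from retinaquant.synthetic_data import CohortSpec, generate_cohort


@pytest.fixture(scope="module")
def dr_cohort():
    spec = CohortSpec(n_control=0, n_dr_normal=600, n_dr_decreased=600,
                      prob_both_eyes=0.5, seed=101)
    df, truth = generate_cohort(spec)
    return df, truth


class TestGroupCompare:
    def test_detects_group_difference(self, dr_cohort):
        df, _ = dr_cohort
        res = group_compare(df, "vd_drcp", "group")
        assert res.p_value < 1e-3
        assert set(res.summaries) == {"dr_normal_bcva", "dr_decreased_bcva"}

    def test_two_group_anova_equals_t_squared(self, rng):
        df = pd.DataFrame({
            "x": rng.normal(size=80),
            "g": ["a"] * 40 + ["b"] * 40,
        })
        t = group_compare(df, "x", "g", test="t")
        f = group_compare(df, "x", "g", test="anova")
        # Welch t vs pooled ANOVA differ slightly; compare pooled t
        t_pooled = stats.ttest_ind(df.x[:40], df.x[40:], equal_var=True)
        assert f.statistic == pytest.approx(t_pooled.statistic**2, rel=1e-9)

    def test_null_p_uniform(self):
        rng = np.random.default_rng(8)
        pvals = []
        for _ in range(300):
            df = pd.DataFrame({
                "x": rng.normal(size=40),
                "g": ["a"] * 20 + ["b"] * 20,
            })
            pvals.append(group_compare(df, "x", "g", test="t").p_value)
        ks = stats.kstest(pvals, "uniform")
        assert ks.pvalue > 0.01

    def test_categorical_uses_chi2(self, dr_cohort):
        df, _ = dr_cohort
        res = group_compare(df, "etdrs_level", "group")
        assert res.test == "chi2"

    def test_constant_parameter_rejected(self):
        df = pd.DataFrame({"x": [1.0] * 20, "g": ["a"] * 10 + ["b"] * 10})
        with pytest.raises(ValueError, match="constant"):
            group_compare(df, "x", "g", test="t")


class TestAdjustedCompare:
    def test_type_i_error_with_zero_group_effect(self):
        # same generating distribution in both arms, strong age effect
        means = {g: dict(m) for g, m in
                 CohortSpec().group_means.items()}
        for g in means:
            means[g] = dict(means["control"])
        rejections = 0
        n_rep = 60
        for rep in range(n_rep):
            spec = CohortSpec(n_control=0, n_dr_normal=75, n_dr_decreased=75,
                              group_means=means, seed=500 + rep)
            df, _ = generate_cohort(spec)
            res = adjusted_group_compare(df, "gcl_ipl_um", "group")
            rejections += res.overall_p < 0.05
        assert rejections / n_rep <= 0.15  # near-nominal size

    def test_covariate_recovery(self):
        # inject a known age slope and recover it
        rng = np.random.default_rng(4)
        n = 400
        age = rng.normal(55, 10, n)
        y = 10 + 0.3 * age + rng.normal(0, 1, n)
        df = pd.DataFrame({
            "y": y, "age": age, "dm_duration": rng.normal(8, 3, n),
            "group": np.where(rng.random(n) < 0.5, "a", "b"),
            "subject_id": [f"S{i}" for i in range(n)],
        })
        X = sm.add_constant(df[["age", "dm_duration"]])
        fit = sm.OLS(df.y, sm.add_constant(
            pd.concat([pd.get_dummies(df.group, drop_first=True).astype(float),
                       df[["age", "dm_duration"]]], axis=1))).fit()
        res = adjusted_group_compare(df, "y", "group")
        assert res.overall_p > 0.001  # no group effect injected
        # adjusted means close between the two groups
        vals = list(res.adjusted_means.values())
        assert abs(vals[0] - vals[1]) < 0.5

    def test_collinear_covariates_rejected(self, dr_cohort):
        df, _ = dr_cohort
        df = df.copy()
        df["age2"] = df["age"]
        with pytest.raises(ValueError, match="collinear"):
            adjusted_group_compare(df, "vd_drcp", "group",
                                   covariates=("age", "age2"))


class TestClusteredRegression:
    def test_singleton_clusters_equal_ols(self):
        df, _ = generate_cohort(
            CohortSpec(n_control=0, n_dr_normal=250, n_dr_decreased=0,
                       prob_both_eyes=0.0, seed=9)
        )
        res = fit_clustered_lm(df, "bcva_logmar", ["age", "vd_drcp", "gcl_ipl_um"])
        X = sm.add_constant(df[["age", "vd_drcp", "gcl_ipl_um"]].astype(float))
        ols = sm.OLS(df["bcva_logmar"], X).fit()
        for name, key in [("const", "intercept"), ("age", "age"),
                          ("vd_drcp", "vd_drcp"), ("gcl_ipl_um", "gcl_ipl_um")]:
            assert res.estimates[key].coefficient == pytest.approx(
                ols.params[name], abs=1e-10
            )

    def test_ci_is_coef_pm_196_se(self, dr_cohort):
        df, _ = dr_cohort
        res = fit_clustered_lm(df, "bcva_logmar", ["age", "vd_drcp"])
        for est in res.estimates.values():
            assert est.ci_lower == pytest.approx(
                est.coefficient - 1.96 * est.standard_error
            )
            assert est.ci_upper == pytest.approx(
                est.coefficient + 1.96 * est.standard_error
            )

    def test_constant_predictor_rejected(self, dr_cohort):
        df, _ = dr_cohort
        df = df.copy()
        df["flat"] = 1.0
        with pytest.raises(ValueError, match="constant"):
            fit_clustered_lm(df, "bcva_logmar", ["flat"])


class TestUnivariateScreen:
    def test_true_predictors_flagged(self, dr_cohort):
        df, _ = dr_cohort
        results = {r.predictors[0]: r for r in univariate_screen(df)}
        for predictor in ("age", "vd_drcp", "gcl_ipl_um"):
            assert results[predictor].notes["significant"], predictor
        # generator signs: age +, deep-plexus density -, GCL-IPL -
        assert results["age"].coefficient("age") > 0
        assert results["vd_drcp"].coefficient("vd_drcp") < 0
        assert results["gcl_ipl_um"].coefficient("gcl_ipl_um") < 0

    def test_pure_noise_size(self):
        # size calibration in the regime where the sandwich asymptotics
        # hold (many clusters); small cluster counts are anticonservative
        rng = np.random.default_rng(15)
        flagged = 0
        n_rep = 100
        for rep in range(n_rep):
            df = pd.DataFrame({
                "noise": rng.normal(size=500),
                "bcva_logmar": rng.normal(size=500),
                "subject_id": [f"S{i}" for i in range(500)],
            })
            res = univariate_screen(df, predictors=("noise",))[0]
            flagged += res.notes["significant"]
        assert flagged / n_rep == pytest.approx(0.05, abs=0.05)


class TestMultivariate:
    def test_recovery_at_scale(self):
        spec = CohortSpec(n_control=0, n_dr_normal=1700, n_dr_decreased=1700,
                          seed=77)
        df, truth = generate_cohort(spec)
        res = multivariate_model(df, ["age", "vd_drcp", "gcl_ipl_um"])
        for key, true in [("intercept", 0.575), ("age", 0.002),
                          ("vd_drcp", -6.194), ("gcl_ipl_um", -0.004)]:
            est = res.estimates[key]
            assert abs(est.coefficient - true) < 2 * est.standard_error, key

    def test_backward_elimination_drops_noise(self, dr_cohort):
        df, _ = dr_cohort
        df = df.copy()
        df["noise"] = np.random.default_rng(1).normal(size=len(df))
        res = multivariate_model(df, ["age", "vd_drcp", "gcl_ipl_um", "noise"])
        assert "noise" in res.notes["eliminated"] or res.p_value("noise") < 0.05

    def test_refit_idempotence(self, dr_cohort):
        # refitting with the retained predictors reproduces coefficients
        df, _ = dr_cohort
        res = multivariate_model(df, ["age", "vd_drcp", "gcl_ipl_um", "eye"])
        refit = fit_clustered_lm(df, "bcva_logmar", res.predictors)
        for name in res.predictors:
            assert refit.coefficient(name) == pytest.approx(
                res.coefficient(name), abs=1e-6
            )

    def test_empty_model_returns_intercept_only(self):
        rng = np.random.default_rng(2)
        df = pd.DataFrame({
            "bcva_logmar": rng.normal(size=100),
            "noise": rng.normal(size=100),
            "subject_id": [f"S{i}" for i in range(100)],
        })
        res = multivariate_model(df, ["noise"])
        assert res.predictors == []
        assert "warning" in res.notes


class TestInteraction:
    def test_product_column_is_centred_product(self, dr_cohort):
        df, _ = dr_cohort
        res = interaction_model(df)
        term = res.notes["interaction_term"]
        assert term == "gcl_ipl_um:vd_drcp"
        # direct construction check happens inside: rebuild and refit
        work = df.copy()
        a = work["gcl_ipl_um"] - work["gcl_ipl_um"].mean()
        b = work["vd_drcp"] - work["vd_drcp"].mean()
        work["manual"] = a * b
        manual = fit_clustered_lm(
            work, "bcva_logmar", ["age", "vd_drcp", "gcl_ipl_um", "manual"]
        )
        assert manual.coefficient("manual") == pytest.approx(
            res.coefficient(term), abs=1e-10
        )

    def test_negative_interaction_detected(self):
        spec = CohortSpec(n_control=0, n_dr_normal=1700, n_dr_decreased=1700,
                          interaction_coefficient=-0.083, seed=13)
        df, _ = generate_cohort(spec)
        res = interaction_model(df)
        term = res.notes["interaction_term"]
        assert res.coefficient(term) < 0
        assert res.p_value(term) < 0.05

    def test_degenerate_product_rejected(self):
        df = pd.DataFrame({
            "bcva_logmar": [0.1, 0.2, 0.3, 0.4],
            "age": [50.0, 51, 52, 53],
            "vd_drcp": [0.07] * 4,
            "gcl_ipl_um": [70.0] * 4,
            "subject_id": list("abcd"),
        })
        with pytest.raises(ValueError, match="zero variance"):
            interaction_model(df)


class TestRoc:
    def test_perfect_separation(self):
        df = pd.DataFrame({
            "x": np.r_[np.zeros(20), np.ones(20)],
            "y": np.r_[np.zeros(20, int), np.ones(20, int)],
        })
        res = roc_cutoff(df, "x", "y")
        assert res.auc == 1.0
        assert res.sensitivity + res.specificity - 1 == pytest.approx(1.0)

    def test_independent_parameter_auc_half(self, rng):
        df = pd.DataFrame({
            "x": rng.normal(size=2000),
            "y": rng.integers(0, 2, size=2000),
        })
        res = roc_cutoff(df, "x", "y")
        assert res.auc == pytest.approx(0.5, abs=0.05)

    def test_auc_equals_u_statistic(self, rng):
        for _ in range(5):
            df = pd.DataFrame({
                "x": rng.normal(size=150),
                "y": rng.integers(0, 2, size=150),
            })
            if df.y.nunique() < 2:
                continue
            res = roc_cutoff(df, "x", "y")
            pos, neg = df.x[df.y == 1], df.x[df.y == 0]
            sign = -1.0 if res.lower_is_abnormal else 1.0
            u = stats.mannwhitneyu(sign * pos, sign * neg).statistic
            assert res.auc == pytest.approx(u / (len(pos) * len(neg)), abs=1e-12)

    def test_direction_autodetected(self, dr_cohort):
        df, _ = dr_cohort
        df = df.copy()
        df["bcva_decreased"] = (df["bcva_logmar"] > 0).astype(int)
        res = roc_cutoff(df, "vd_drcp")
        assert res.lower_is_abnormal
        assert res.auc > 0.5

    def test_single_class_rejected(self):
        df = pd.DataFrame({"x": [1.0, 2.0], "y": [1, 1]})
        with pytest.raises(ValueError, match="both classes"):
            roc_cutoff(df, "x", "y")
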