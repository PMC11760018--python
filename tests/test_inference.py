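"""Cohort-level statistics: proportions, t/z-tests, metrics, logistic models."""

import math

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm
from scipy import stats

from icuews import (
    ConfusionMatrix,
    InvalidParameterError,
    PatientRecord,
    anova_deviance,
    combined_strength,
    fit_logistic,
    metrics_from_confusion,
    proportion_table,
    roc_auc_positive_tau,
    stratify_match,
    two_proportion_ztest,
    welch_ttest,
)
from icuews.inference import MODEL_PREDICTORS, build_design_table
from icuews.trend import RecordOutcome, TrendResult


def _outcome(pid, cohort, ward, sig=None, taus=None):
    o = RecordOutcome(patient_id=pid, cohort=cohort, ward=ward)
    sig = sig or {}
    taus = taus or {}
    for key in sig.keys() | taus.keys():
        var, ind = key
        o.results[key] = TrendResult(
            variable=var, indicator=ind, n=60, tau=taus.get(key, 0.0),
            s_statistic=0.0, var_s=1.0, z=0.0, p=0.5,
            significant_increase=sig.get(key, False),
        )
    return o


def _rec(pid, age, cohort=2):
    return PatientRecord(
        patient_id=pid, cohort=cohort, ward="PICU", age=age, sex="M",
        extubation_time=0.0, endpoint_time=7200.0, death_flag=False,
    )


class TestProportions:
    def test_counts_and_whole_row(self):
        outcomes = [
            _outcome(f"a{i}", 1, "PICU", sig={("HR", "variance"): i < 3})
            for i in range(10)
        ]
        table = proportion_table(outcomes, variables=["HR"], indicators=["variance"])
        whole = table[(table["ward"] == "Whole")].iloc[0]
        assert whole["n_evaluable"] == 10
        assert whole["n_significant"] == 3
        assert whole["proportion"] == pytest.approx(0.3)

    def test_zero_evaluable_marked_unavailable(self):
        outcomes = [_outcome("a", 1, "PICU", sig={("HR", "variance"): True})]
        table = proportion_table(outcomes, variables=["ABP"], indicators=["variance"])
        assert np.isnan(table[table["ward"] == "Whole"]["proportion"]).all()


class TestTwoProportionZ:
    def test_published_counts_worked_example(self):
        """24/101 vs 253/1475 significant increases: z ~ 1.69, one-sided p < .05."""
        z, p = two_proportion_ztest(24, 101, 253, 1475)
        assert z == pytest.approx(1.69, abs=0.01)
        assert p == pytest.approx(0.046, abs=0.001)
        assert p < 0.05

    def test_equal_proportions(self):
        z, p = two_proportion_ztest(10, 100, 10, 100)
        assert z == 0.0 and p == pytest.approx(0.5)

    def test_degenerate_pooled(self):
        assert two_proportion_ztest(0, 50, 0, 60) == (0.0, 1.0)
        assert two_proportion_ztest(50, 50, 60, 60) == (0.0, 1.0)

    def test_agrees_with_closed_form(self):
        k1, n1, k2, n2 = 30, 120, 40, 300
        z, _ = two_proportion_ztest(k1, n1, k2, n2)
        pooled = (k1 + k2) / (n1 + n2)
        expected = (k1 / n1 - k2 / n2) / math.sqrt(
            pooled * (1 - pooled) * (1 / n1 + 1 / n2)
        )
        assert z == pytest.approx(expected)


class TestWelch:
    def test_published_summary_worked_example(self):
        """Whole-cohort heart-rate AC tau summaries give two-sided p ~ 0.011."""
        t, df, p = welch_ttest((0.069, 0.036, 101), (-0.027, 0.009, 1475))
        assert p == pytest.approx(0.011, abs=5e-4)
        assert t > 0

    def test_identical_samples(self):
        x = np.arange(10.0)
        t, _, p = welch_ttest(x, x)
        assert t == 0.0 and p == pytest.approx(1.0)

    def test_agrees_with_scipy_on_arrays(self):
        rng = np.random.default_rng(0)
        a, b = rng.normal(size=40), rng.normal(0.5, 2.0, size=25)
        t, df, p = welch_ttest(a, b)
        ref = stats.ttest_ind(a, b, equal_var=False)
        assert t == pytest.approx(ref.statistic)
        assert p == pytest.approx(ref.pvalue)

    def test_null_p_uniform(self):
        rng = np.random.default_rng(5)
        ps = [
            welch_ttest(rng.normal(size=50), rng.normal(size=50))[2]
            for _ in range(300)
        ]
        assert stats.kstest(ps, "uniform").pvalue > 0.01

    def test_zero_se_rejected(self):
        with pytest.raises(InvalidParameterError):
            welch_ttest((0.0, 0.0, 10), (1.0, 0.0, 10))


class TestConfusionMetrics:
    def test_published_confusion_row(self):
        m = metrics_from_confusion(ConfusionMatrix(tp=24, fp=253, fn=77, tn=1222))
        assert round(m.ppv, 3) == 0.087
        assert round(m.npv, 3) == 0.941
        assert round(m.sensitivity, 3) == 0.238
        assert round(m.specificity, 3) == 0.828
        assert round(m.balanced_accuracy, 3) == 0.533

    def test_perfect_classifier(self):
        m = metrics_from_confusion(ConfusionMatrix(tp=10, fp=0, fn=0, tn=20))
        assert (m.ppv, m.npv, m.sensitivity, m.specificity, m.balanced_accuracy) == (
            1.0, 1.0, 1.0, 1.0, 1.0,
        )

    def test_degenerate_counts_give_nan(self):
        m = metrics_from_confusion(ConfusionMatrix(tp=0, fp=0, fn=5, tn=10))
        assert math.isnan(m.ppv)
        assert m.specificity == 1.0

    def test_confusion_from_outcomes(self):
        from icuews import confusion_and_metrics

        outcomes = [
            _outcome("a", 1, "PICU", sig={("HR", "variance"): True}),
            _outcome("b", 1, "PICU", sig={("HR", "variance"): False}),
            _outcome("c", 2, "PICU", sig={("HR", "variance"): True}),
            _outcome("d", 2, "PICU", sig={("HR", "variance"): False}),
            _outcome("e", 3, "PICU", sig={("HR", "variance"): True}),  # ignored
            _outcome("f", 2, "PICU", sig={("RR", "variance"): True}),  # other var
        ]
        cm, m = confusion_and_metrics(outcomes, "HR", "variance")
        assert (cm.tp, cm.fp, cm.fn, cm.tn) == (1, 1, 1, 1)
        assert m.sensitivity == 0.5 and m.specificity == 0.5

    def test_balanced_accuracy_identity(self):
        m = metrics_from_confusion(ConfusionMatrix(tp=7, fp=13, fn=3, tn=40))
        assert m.balanced_accuracy == pytest.approx((m.sensitivity + m.specificity) / 2)


class TestPositiveTauROC:
    def test_perfect_separation(self):
        taus = [0.8, 0.7, 0.6, 0.3, 0.2, 0.1]
        labels = [True, True, True, False, False, False]
        _, _, auc = roc_auc_positive_tau(taus, labels)
        assert auc == 1.0

    def test_permuted_labels_chance_level(self):
        rng = np.random.default_rng(3)
        taus = rng.uniform(-1, 1, 400)
        aucs = []
        for _ in range(50):
            labels = rng.permutation([True] * 40 + [False] * 360)
            aucs.append(roc_auc_positive_tau(taus, labels)[2])
        assert np.mean(aucs) == pytest.approx(0.5, abs=0.03)

    def test_all_negative_taus_chance_by_convention(self):
        _, _, auc = roc_auc_positive_tau([-0.5, -0.2, -0.1], [True, False, False])
        assert auc == 0.5

    def test_negative_taus_never_predicted_positive(self):
        """A failure record with negative tau cannot raise AUC above one whose
        tau is small but positive: both sit below every threshold equally."""
        base = roc_auc_positive_tau([0.5, -0.9, 0.3, 0.2], [True, True, False, False])[2]
        alt = roc_auc_positive_tau([0.5, -0.1, 0.3, 0.2], [True, True, False, False])[2]
        assert base == alt

    def test_monotone_transform_invariance(self):
        rng = np.random.default_rng(11)
        taus = rng.uniform(-1, 1, 200)
        labels = rng.random(200) < stats.norm.cdf(taus * 2)
        if labels.all() or not labels.any():
            pytest.skip("degenerate permutation")
        a1 = roc_auc_positive_tau(taus, labels)[2]
        transformed = np.where(taus > 0, taus**3, taus)  # monotone on tau > 0
        a2 = roc_auc_positive_tau(transformed, labels)[2]
        assert a1 == pytest.approx(a2)

    def test_single_class_rejected(self):
        with pytest.raises(InvalidParameterError):
            roc_auc_positive_tau([0.1, 0.2], [True, True])


class TestCombinedStrength:
    def test_positive_part_sum(self):
        assert combined_strength([0.2, -0.5, 0.1]) == pytest.approx(0.3)

    def test_all_nonpositive(self):
        assert combined_strength([-0.2, 0.0, -0.9]) == 0.0

    def test_nan_ignored(self):
        assert combined_strength([0.2, float("nan")]) == pytest.approx(0.2)

    def test_empty_rejected(self):
        with pytest.raises(InvalidParameterError):
            combined_strength([])


class TestStratifyMatch:
    def test_disjoint_case_ages_select_matching_controls(self, rng):
        cases = [_rec(f"c{i}", 0.5, cohort=1) for i in range(10)]
        controls = [_rec(f"k{i}", age) for i, age in enumerate(np.linspace(0.1, 17.9, 200))]
        matched = stratify_match(cases, controls, rng)
        assert matched and all(r.age < 2.5 for r in matched)

    @pytest.mark.parametrize("seed", [1, 2, 3])
    def test_matched_age_distribution_not_distinguishable(self, seed):
        rng = np.random.default_rng(seed)
        cases = [_rec(f"c{i}", a, cohort=1) for i, a in enumerate(rng.uniform(0, 10, 60))]
        controls = [_rec(f"k{i}", a) for i, a in enumerate(rng.uniform(0, 18, 800))]
        matched = stratify_match(cases, controls, rng, n_bins=6)
        edges = np.linspace(0, 18.001, 7)
        case_h = np.histogram([r.age for r in cases], bins=edges)[0]
        match_h = np.histogram([r.age for r in matched], bins=edges)[0]
        mask = case_h > 0
        scaled = case_h[mask] * match_h.sum() / case_h.sum()
        chi2 = ((match_h[mask] - scaled) ** 2 / np.maximum(scaled, 1e-9)).sum()
        p = stats.chi2.sf(chi2, mask.sum() - 1)
        assert p > 0.05

    def test_empty_cohort_rejected(self, rng):
        with pytest.raises(InvalidParameterError):
            stratify_match([], [_rec("k", 1.0)], rng)

    def test_missing_control_bin_warns(self, rng):
        cases = [_rec("c0", 17.0, cohort=1), _rec("c1", 1.0, cohort=1)]
        controls = [_rec(f"k{i}", 1.0) for i in range(10)]
        with pytest.warns(UserWarning, match="no controls"):
            stratify_match(cases, controls, rng)


def _simulate_design(rng, n, betas, weights_informative=False):
    cols = MODEL_PREDICTORS[1]
    X = rng.normal(size=(n, len(cols)))
    eta = betas[0] + X @ np.asarray(betas[1:])
    y = rng.random(n) < 1.0 / (1.0 + np.exp(-eta))
    df = pd.DataFrame(X, columns=cols)
    df["outcome"] = y.astype(int)
    return df


class TestLogistic:
    def test_null_data_near_zero_coefficients(self):
        rng = np.random.default_rng(21)
        design = _simulate_design(rng, 1000, [-1.0, 0.0, 0.0])
        fit = fit_logistic(1, design, weight_failure=1.0)
        for name in MODEL_PREDICTORS[1]:
            coef = fit.coefficients.loc[name]
            assert abs(coef["estimate"]) < 3 * coef["se"]
        assert fit.nagelkerke_r2 < 0.02

    def test_recovers_generative_coefficients(self):
        rng = np.random.default_rng(22)
        betas = [-2.0, 1.0, -0.5]
        design = _simulate_design(rng, 2000, betas)
        fit = fit_logistic(1, design, weight_failure=1.0)
        for true, name in zip(betas, ["intercept"] + MODEL_PREDICTORS[1]):
            coef = fit.coefficients.loc[name]
            assert abs(coef["estimate"] - true) < 2 * coef["se"]

    def test_unit_weights_equal_unweighted_fit(self):
        rng = np.random.default_rng(23)
        design = _simulate_design(rng, 500, [-1.0, 0.8, 0.0])
        fit = fit_logistic(1, design, weight_failure=1.0, weight_success=1.0)
        X = sm.add_constant(design[MODEL_PREDICTORS[1]].to_numpy())
        ref = sm.Logit(design["outcome"].to_numpy(), X).fit(disp=0)
        np.testing.assert_allclose(
            fit.coefficients["estimate"].to_numpy(), ref.params, rtol=1e-5
        )

    def test_aic_identity_and_weighting(self):
        rng = np.random.default_rng(24)
        design = _simulate_design(rng, 600, [-1.5, 1.0, 0.3])
        fit = fit_logistic(1, design)  # 10:1 weighting
        k = len(MODEL_PREDICTORS[1]) + 1
        assert fit.aic == pytest.approx(fit.deviance + 2 * k, rel=1e-6)
        assert fit.aic == pytest.approx(-2 * fit.loglik + 2 * k, rel=1e-6)
        assert 0.0 <= fit.nagelkerke_r2 <= 1.0
        assert fit.n == 600  # unweighted row count

    def test_informative_predictor_lowers_aic(self):
        rng = np.random.default_rng(25)
        cols4 = MODEL_PREDICTORS[4]
        X = rng.normal(size=(800, len(cols4)))
        eta = -1.0 + 1.2 * X[:, 0] + 0.9 * X[:, 3]
        y = rng.random(800) < 1.0 / (1.0 + np.exp(-eta))
        design = pd.DataFrame(X, columns=cols4)
        design["outcome"] = y.astype(int)
        fit1 = fit_logistic(1, design)   # HR taus only (includes X[:,0])
        fit4 = fit_logistic(4, design)   # all six taus
        assert fit4.aic < fit1.aic

    def test_complete_case_rows(self):
        rng = np.random.default_rng(26)
        design = _simulate_design(rng, 300, [-1.0, 0.5, 0.0])
        design.loc[:49, MODEL_PREDICTORS[1][0]] = np.nan
        fit = fit_logistic(1, design, weight_failure=1.0)
        assert fit.n == 250


class TestAnovaDeviance:
    def test_identity_on_same_model(self):
        rng = np.random.default_rng(30)
        design = _simulate_design(rng, 400, [-1.0, 1.0, 0.0])
        fit = fit_logistic(1, design)
        dev, df, p = anova_deviance(fit, fit)
        assert dev == pytest.approx(0.0) and df == 0 and p == 1.0

    def test_informative_nested_comparison(self):
        rng = np.random.default_rng(31)
        cols4 = MODEL_PREDICTORS[4]
        X = rng.normal(size=(1500, len(cols4)))
        eta = -1.0 + 1.0 * X[:, 2] + 0.8 * X[:, 5]
        y = rng.random(1500) < 1.0 / (1.0 + np.exp(-eta))
        design = pd.DataFrame(X, columns=cols4)
        design["outcome"] = y.astype(int)
        nested = fit_logistic(1, design)
        full = fit_logistic(4, design)
        dev, df, p = anova_deviance(nested, full)
        assert df == 4
        assert dev == pytest.approx(2 * (full.loglik - nested.loglik), rel=1e-6)
        assert p < 0.001

    def test_non_nested_rejected(self):
        rng = np.random.default_rng(32)
        cols = MODEL_PREDICTORS[6]
        X = rng.normal(size=(300, len(cols)))
        design = pd.DataFrame(X, columns=cols)
        design["outcome"] = (rng.random(300) < 0.3).astype(int)
        fit1 = fit_logistic(1, design)
        fit5 = fit_logistic(5, design)
        with pytest.raises(InvalidParameterError):
            anova_deviance(fit1, fit5)


class TestDesignTable:
    def test_tau_and_mean_columns(self):
        outcomes = [
            _outcome("a", 1, "PICU", taus={("HR", "autocorrelation"): 0.4, ("HR", "variance"): -0.1}),
            _outcome("b", 2, "PICU", taus={("RR", "variance"): 0.2}),
            _outcome("c", 3, "PICU", taus={("HR", "variance"): 0.2}),  # excluded
        ]
        means = {"a": {"HR": 110.0}, "b": {"RR": 28.0}}
        table = build_design_table(outcomes, means=means)
        assert len(table) == 2
        row_a = table[table["patient_id"] == "a"].iloc[0]
        assert row_a["outcome"] == 1
        assert row_a["HR_r1_tau"] == pytest.approx(0.4)
        assert row_a["HR_mean"] == pytest.approx(110.0)
        assert np.isnan(row_a["RR_var_tau"])
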