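"""Cohort-level statistics and predictive evaluation.

Given per-record trend outcomes this module produces the cohort comparisons
of the analysis design: age-stratified control matching, proportions of
significant increases with two-proportion z-tests, Welch t-tests on the
Kendall-tau distributions, confusion matrices with PPV/NPV/sensitivity/
specificity/balanced accuracy, positive-tau ROC curves and AUC, a combined
positive-tau strength score, weighted logistic regression models, and
deviance ANOVA between nested models.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from sklearn.metrics import auc as _trapezoid_auc
from sklearn.metrics import roc_curve as _sk_roc_curve

from .synthetic import InvalidParameterError, PatientRecord, VARIABLES
from .trend import INDICATORS, RecordOutcome

__all__ = [
    "ConfusionMatrix",
    "MetricsRow",
    "LogisticFit",
    "stratify_match",
    "proportion_table",
    "two_proportion_ztest",
    "welch_ttest",
    "metrics_from_confusion",
    "confusion_and_metrics",
    "roc_auc_positive_tau",
    "combined_strength",
    "build_design_table",
    "fit_logistic",
    "anova_deviance",
    "MODEL_PREDICTORS",
]


# ---------------------------------------------------------------------------
# stratification

def stratify_match(
    cases: Sequence[PatientRecord],
    controls: Sequence[PatientRecord],
    rng: np.random.Generator,
    n_bins: int = 8,
) -> list[PatientRecord]:
    """Subsample controls so their binned age distribution matches the cases'.

    Ages are binned on a common uniform grid; within each bin, controls are
    subsampled (without replacement, seeded) so that per-bin proportions
    follow the cases'.  The matched set is made as large as the scarcest bin
    allows.  Bins holding cases but no controls trigger a warning and are
    matched with whatever is available (nothing).
    """
    if not cases or not controls:
        raise InvalidParameterError("both cohorts must be non-empty")
    case_ages = np.array([r.age for r in cases])
    ctrl_ages = np.array([r.age for r in controls])
    hi = max(case_ages.max(), ctrl_ages.max()) + 1e-9
    edges = np.linspace(0.0, hi, n_bins + 1)
    case_bins = np.clip(np.digitize(case_ages, edges) - 1, 0, n_bins - 1)
    ctrl_bins = np.clip(np.digitize(ctrl_ages, edges) - 1, 0, n_bins - 1)

    case_counts = np.bincount(case_bins, minlength=n_bins)
    ctrl_counts = np.bincount(ctrl_bins, minlength=n_bins)
    ratios = []
    for b in range(n_bins):
        if case_counts[b] == 0:
            continue
        if ctrl_counts[b] == 0:
            warnings.warn(f"age bin {b}: cases present but no controls", stacklevel=2)
            continue
        ratios.append(ctrl_counts[b] / case_counts[b])
    ratio = min(ratios) if ratios else 0.0

    matched: list[PatientRecord] = []
    for b in range(n_bins):
        take = int(math.floor(ratio * case_counts[b]))
        pool = np.flatnonzero(ctrl_bins == b)
        take = min(take, len(pool))
        if take > 0:
            chosen = rng.choice(pool, size=take, replace=False)
            matched.extend(controls[i] for i in sorted(chosen))
    return matched


# ---------------------------------------------------------------------------
# proportions and location tests

def proportion_table(
    outcomes: Sequence[RecordOutcome],
    variables: Sequence[str] = VARIABLES,
    indicators: Sequence[str] = INDICATORS,
    by_ward: bool = True,
) -> pd.DataFrame:
    """Proportion of significant increases per (cohort, ward, variable, indicator).

    A record is evaluable for a cell when its trend test for that
    (variable, indicator) exists; the proportion is significant-increase
    count over evaluable count.  A 'Whole' ward row aggregates all wards.
    """
    wards = (["PICU", "CICU", "NICU"] if by_ward else []) + ["Whole"]
    rows = []
    cohorts = sorted({o.cohort for o in outcomes})
    for cohort in cohorts:
        for ward in wards:
            subset = [
                o
                for o in outcomes
                if o.cohort == cohort and (ward == "Whole" or o.ward == ward)
            ]
            for variable in variables:
                for indicator in indicators:
                    results = [
                        o.results[(variable, indicator)]
                        for o in subset
                        if (variable, indicator) in o.results
                    ]
                    n = len(results)
                    k = sum(r.significant_increase for r in results)
                    rows.append(
                        {
                            "cohort": cohort,
                            "ward": ward,
                            "variable": variable,
                            "indicator": indicator,
                            "n_evaluable": n,
                            "n_significant": k,
                            "proportion": k / n if n else np.nan,
                        }
                    )
    return pd.DataFrame(rows)


def two_proportion_ztest(
    k1: int, n1: int, k2: int, n2: int, alternative: str = "greater"
) -> tuple[float, float]:
    """Pooled two-proportion z-test.

    z = (p1 - p2) / sqrt(phat (1 - phat) (1/n1 + 1/n2)) with the pooled
    phat = (k1 + k2) / (n1 + n2).  ``alternative='greater'`` tests whether
    the first proportion (failure cohort) exceeds the second.  Degenerate
    pooled proportions (0 or 1) carry no evidence and return p = 1.
    """
    if n1 <= 0 or n2 <= 0:
        raise InvalidParameterError("sample sizes must be positive")
    p1, p2 = k1 / n1, k2 / n2
    pooled = (k1 + k2) / (n1 + n2)
    if pooled <= 0.0 or pooled >= 1.0:
        return 0.0, 1.0
    z = (p1 - p2) / math.sqrt(pooled * (1.0 - pooled) * (1.0 / n1 + 1.0 / n2))
    if alternative == "greater":
        p = float(stats.norm.sf(z))
    elif alternative == "less":
        p = float(stats.norm.cdf(z))
    elif alternative == "two-sided":
        p = float(2.0 * stats.norm.sf(abs(z)))
    else:
        raise InvalidParameterError(f"unknown alternative {alternative!r}")
    return float(z), p


def welch_ttest(
    sample1,
    sample2,
    alternative: str = "two-sided",
) -> tuple[float, float, float]:
    """Welch's unequal-variance t-test from samples or summary statistics.

    Each argument is either a 1-d array of observations or a
    ``(mean, standard_error, n)`` triple.  Returns ``(t, df, p)`` with the
    Welch-Satterthwaite degrees of freedom.  ``alternative='greater'`` tests
    whether the first mean exceeds the second.
    """

    def _summarize(s) -> tuple[float, float, int]:
        if isinstance(s, tuple) and len(s) == 3:
            return float(s[0]), float(s[1]), int(s[2])
        arr = np.asarray(s, dtype=float)
        if len(arr) < 2:
            raise InvalidParameterError("samples need at least 2 observations")
        return float(arr.mean()), float(arr.std(ddof=1) / math.sqrt(len(arr))), len(arr)

    m1, se1, n1 = _summarize(sample1)
    m2, se2, n2 = _summarize(sample2)
    pooled = se1**2 + se2**2
    if pooled <= 0:
        raise InvalidParameterError("zero pooled standard error")
    t = (m1 - m2) / math.sqrt(pooled)
    df = pooled**2 / (se1**4 / (n1 - 1) + se2**4 / (n2 - 1))
    if alternative == "two-sided":
        p = float(2.0 * stats.t.sf(abs(t), df))
    elif alternative == "greater":
        p = float(stats.t.sf(t, df))
    elif alternative == "less":
        p = float(stats.t.cdf(t, df))
    else:
        raise InvalidParameterError(f"unknown alternative {alternative!r}")
    return float(t), float(df), p


# ---------------------------------------------------------------------------
# classification metrics

@dataclass(frozen=True)
class ConfusionMatrix:
    """Counts with extubation failure as the positive class."""

    tp: int
    fp: int
    fn: int
    tn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.fn, self.tn) < 0:
            raise InvalidParameterError("confusion counts must be nonnegative")


@dataclass(frozen=True)
class MetricsRow:
    """Classification metrics; NaN marks an undefined (0/0) ratio."""

    ppv: float
    npv: float
    sensitivity: float
    specificity: float
    balanced_accuracy: float
    auc: float = float("nan")


def _ratio(num: int, den: int) -> float:
    return num / den if den else float("nan")


def metrics_from_confusion(cm: ConfusionMatrix) -> MetricsRow:
    """PPV, NPV, sensitivity, specificity and balanced accuracy from counts."""
    sens = _ratio(cm.tp, cm.tp + cm.fn)
    spec = _ratio(cm.tn, cm.tn + cm.fp)
    return MetricsRow(
        ppv=_ratio(cm.tp, cm.tp + cm.fp),
        npv=_ratio(cm.tn, cm.tn + cm.fn),
        sensitivity=sens,
        specificity=spec,
        balanced_accuracy=(sens + spec) / 2.0,
    )


def confusion_and_metrics(
    outcomes: Sequence[RecordOutcome], variable: str, indicator: str
) -> tuple[ConfusionMatrix, MetricsRow]:
    """Confusion matrix and metrics for one indicator, cohort 1 vs cohort 2.

    Prediction = significant increase of the chosen indicator; truth =
    cohort-1 membership (extubation failure).
    """
    tp = fp = fn = tn = 0
    for o in outcomes:
        res = o.results.get((variable, indicator))
        if res is None or o.cohort not in (1, 2):
            continue
        predicted = res.significant_increase
        if o.cohort == 1:
            tp, fn = tp + predicted, fn + (not predicted)
        else:
            fp, tn = fp + predicted, tn + (not predicted)
    cm = ConfusionMatrix(tp=tp, fp=fp, fn=fn, tn=tn)
    return cm, metrics_from_confusion(cm)


def roc_auc_positive_tau(
    taus: Sequence[float], labels: Sequence[bool]
) -> tuple[np.ndarray, np.ndarray, float]:
    """ROC curve and AUC from Kendall tau scores, positive trends only.

    Records with tau <= 0 are assigned a common sentinel below every
    threshold, so they are never predicted positive: only the strength of a
    *positive* trend is treated as evidence of an approaching transition.
    Thresholds sweep the observed positive tau values plus extremes; AUC is
    the trapezoid area.  If no tau is positive the classifier is
    uninformative and AUC is 0.5 by convention.
    """
    taus = np.asarray(taus, dtype=float)
    labels = np.asarray(labels, dtype=bool)
    if labels.all() or not labels.any():
        raise InvalidParameterError("both classes must be present")
    scores = np.where(taus > 0, taus, -1.0)
    if not (taus > 0).any():
        return np.array([0.0, 1.0]), np.array([0.0, 1.0]), 0.5
    fpr, tpr, _ = _sk_roc_curve(labels.astype(int), scores)
    return fpr, tpr, float(_trapezoid_auc(fpr, tpr))


def combined_strength(taus: Mapping | Sequence[float]) -> float:
    """Combined strength of positive trends: sum of positive tau values.

    Accepts the record's available tau coefficients (both indicators of all
    variables by default, i.e. the predictors of the all-tau logistic
    model); negative taus contribute nothing.
    """
    values = list(taus.values()) if isinstance(taus, Mapping) else list(taus)
    if not values:
        raise InvalidParameterError("at least one tau required")
    return float(sum(max(t, 0.0) for t in values if not math.isnan(t)))


# ---------------------------------------------------------------------------
# logistic models

TAU_COLUMNS = [f"{v}_{ind}_tau" for v in VARIABLES for ind in ("r1", "var")]
MEAN_COLUMNS = [f"{v}_mean" for v in VARIABLES]

#: Predictor sets of the six logistic models: per-variable tau pairs (1-3),
#: all tau coefficients (4), vital-sign means only (5), everything (6).
MODEL_PREDICTORS: dict[int, list[str]] = {
    1: ["HR_r1_tau", "HR_var_tau"],
    2: ["RR_r1_tau", "RR_var_tau"],
    3: ["ABP_r1_tau", "ABP_var_tau"],
    4: list(TAU_COLUMNS),
    5: list(MEAN_COLUMNS),
    6: list(TAU_COLUMNS) + list(MEAN_COLUMNS),
}


@dataclass
class LogisticFit:
    """A fitted weighted logistic model and its summary statistics."""

    model_id: int
    predictors: list[str]
    coefficients: pd.DataFrame  # index: const + predictors; cols: estimate, se, z, p
    n: int                      # unweighted complete-case row count
    aic: float
    nagelkerke_r2: float
    deviance: float
    loglik: float
    loglik_null: float
    converged: bool = True
    weights: np.ndarray | None = None
    row_index: np.ndarray | None = None


def build_design_table(
    outcomes: Sequence[RecordOutcome],
    means: Mapping[str, Mapping[str, float]] | None = None,
) -> pd.DataFrame:
    """Assemble the per-record design table for the logistic models.

    One row per cohort-1/2 record: the outcome flag (failure = 1), the six
    Kendall-tau coefficients, and optionally the per-variable raw-series
    means (``means[patient_id][variable]``).  Missing entries are NaN;
    model fitting is complete-case on each model's predictors.
    """
    rows = []
    for o in outcomes:
        if o.cohort not in (1, 2):
            continue
        row: dict = {"patient_id": o.patient_id, "outcome": int(o.cohort == 1)}
        for variable in VARIABLES:
            res_ac = o.results.get((variable, "autocorrelation"))
            res_var = o.results.get((variable, "variance"))
            row[f"{variable}_r1_tau"] = res_ac.tau if res_ac else np.nan
            row[f"{variable}_var_tau"] = res_var.tau if res_var else np.nan
            if means is not None:
                row[f"{variable}_mean"] = means.get(o.patient_id, {}).get(
                    variable, np.nan
                )
        rows.append(row)
    return pd.DataFrame(rows)


def fit_logistic(
    model_id: int,
    design: pd.DataFrame,
    weight_failure: float = 10.0,
    weight_success: float = 1.0,
) -> LogisticFit:
    """Fit one of the six logistic models by weighted maximum likelihood.

    Failures (the rarer class) receive weight 10 and successes weight 1 by
    default, applied multiplicatively in the log-likelihood (frequency
    weights).  Rows with any missing predictor are dropped (complete-case),
    so the all-variable models fit on fewer rows.  AIC uses the weighted
    likelihood; the pseudo-R^2 is Nagelkerke's

        R^2 = [1 - (L0/L1)^(2/n)] / [1 - L0^(2/n)]

    with L0 the weighted intercept-only likelihood on the same rows and n
    the unweighted row count.
    """
    predictors = MODEL_PREDICTORS[model_id]
    missing = [c for c in predictors if c not in design.columns]
    if missing:
        raise InvalidParameterError(f"design table lacks columns {missing}")
    sub = design[["outcome"] + predictors].dropna()
    n = len(sub)
    if n < len(predictors) + 1:
        raise InvalidParameterError("too few complete-case rows")
    y = sub["outcome"].to_numpy(dtype=float)
    X = sm.add_constant(sub[predictors].to_numpy(dtype=float))
    w = np.where(y == 1.0, weight_failure, weight_success)

    model = sm.GLM(y, X, family=sm.families.Binomial(), freq_weights=w)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        fit = model.fit()
    # Separation shows up as exploding slopes/standard errors; the intercept
    # is excluded since distant predictor scales legitimately inflate it.
    if (
        not getattr(fit, "converged", True)
        or np.any(~np.isfinite(fit.bse))
        or np.any(fit.bse > 1e3)
        or np.any(np.abs(fit.params[1:]) > 50.0)
    ):
        raise RuntimeError(
            f"model {model_id}: weighted logistic fit did not converge "
            "(possible separation)"
        )
    null_fit = sm.GLM(
        y, np.ones((n, 1)), family=sm.families.Binomial(), freq_weights=w
    ).fit()

    ll1, ll0 = float(fit.llf), float(null_fit.llf)
    denom = 1.0 - math.exp(2.0 * ll0 / n)
    nagelkerke = (1.0 - math.exp(2.0 * (ll0 - ll1) / n)) / denom if denom else float("nan")
    coefficients = pd.DataFrame(
        {
            "estimate": fit.params,
            "se": fit.bse,
            "z": fit.tvalues,
            "p": fit.pvalues,
        },
        index=["intercept"] + predictors,
    )
    return LogisticFit(
        model_id=model_id,
        predictors=list(predictors),
        coefficients=coefficients,
        n=n,
        aic=float(fit.aic),
        nagelkerke_r2=float(np.clip(nagelkerke, 0.0, 1.0)),
        deviance=float(fit.deviance),
        loglik=ll1,
        loglik_null=ll0,
        converged=True,
        weights=w,
        row_index=sub.index.to_numpy(),
    )


def anova_deviance(fit_nested: LogisticFit, fit_full: LogisticFit) -> tuple[float, int, float]:
    """Deviance ANOVA between two nested weighted logistic fits.

    Returns (deviance difference, df difference, chi-square p).  Both fits
    must use the same rows and weights and the nested model's predictors
    must be a subset of the full model's.
    """
    if not set(fit_nested.predictors) <= set(fit_full.predictors):
        raise InvalidParameterError("models are not nested")
    if fit_nested.n != fit_full.n or (
        fit_nested.row_index is not None
        and fit_full.row_index is not None
        and not np.array_equal(fit_nested.row_index, fit_full.row_index)
    ):
        raise InvalidParameterError("fits must use identical rows")
    dev_diff = fit_nested.deviance - fit_full.deviance
    df_diff = len(fit_full.predictors) - len(fit_nested.predictors)
    if df_diff == 0:
        return float(dev_diff), 0, 1.0
    p = float(stats.chi2.sf(dev_diff, df_diff))
    return float(dev_diff), int(df_diff), p
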