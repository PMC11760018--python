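"""End-to-end pipeline: preprocess -> indicators -> trend tests -> cohort stats.

`run_pipeline` binds the stages into one deterministic run driven by a
`RunConfig`: for every configured window size and cohort pair it produces
the full report set — evaluable counts, proportions of significant
increases with z-tests, Kendall-tau summaries with Welch t-tests, confusion
metrics with positive-tau AUC, the combined-strength comparison, and (for
the primary failure-vs-control pair) the six weighted logistic models with
deviance ANOVA.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from . import inference, io as _io
from .ews import WindowSpec, compute_ews_trace
from .preprocess import (
    DEFAULT_KERNEL_SD_S,
    DEFAULT_MIN_DURATION_S,
    EmptySeriesError,
    eligibility_filter,
    handle_gaps,
    preprocess_series,
)
from .synthetic import CohortConfig, PatientRecord, VARIABLES, VitalSignSeries, generate_cohort
from .trend import INDICATORS, RecordOutcome, evaluate_record

logger = logging.getLogger("icuews")

__all__ = ["RunConfig", "PipelineResult", "run_pipeline"]


@dataclass
class RunConfig:
    """Configuration of one analysis run.

    ``cohort_pairs`` lists (case cohort, control cohort) comparisons; the
    primary analysis is (1, 2).  ``welch_alternative`` is two-sided by
    default for the tau-summary tables, with one-sided available;
    ``ztest_alternative`` defaults to one-sided (case proportion greater).
    """

    seed: int = 0
    window_minutes: tuple[float, ...] = (60.0,)
    alpha: float = 0.05
    kernel_sd_s: float = DEFAULT_KERNEL_SD_S
    min_duration_s: float = DEFAULT_MIN_DURATION_S
    max_fill_gap: int = 10
    cohort_pairs: tuple[tuple[int, int], ...] = ((1, 2),)
    ward_split: bool = True
    stratify_age: bool = True
    age_bins: int = 8
    mk_alternative: str = "increase"
    ztest_alternative: str = "greater"
    welch_alternative: str = "two-sided"
    combined_tau_both_indicators: bool = True
    weight_failure: float = 10.0
    dataset_manifest: str | None = None
    generator: CohortConfig = field(default_factory=CohortConfig)

    def __post_init__(self) -> None:
        if not 0.0 < self.alpha < 1.0:
            raise ValueError("alpha must be in (0, 1)")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        gen = raw.pop("generator", None)
        cfg = cls(**{k: v for k, v in raw.items() if k in {f.name for f in dataclasses.fields(cls)}})
        if gen:
            cfg.generator = CohortConfig(**gen)
        if "window_minutes" in raw:
            cfg.window_minutes = tuple(raw["window_minutes"])
        if "cohort_pairs" in raw:
            cfg.cohort_pairs = tuple(tuple(p) for p in raw["cohort_pairs"])
        return cfg

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(_io._config_to_jsonable(self), fh, sort_keys=True)


@dataclass
class PipelineResult:
    """All tables and accounting produced by one run."""

    config: RunConfig
    manifest: dict
    exclusions: list[dict]
    outcomes: dict[float, list[RecordOutcome]]  # per window size
    tables: dict[str, pd.DataFrame]
    logistic_fits: dict[float, dict[int, inference.LogisticFit]]
    anova: dict[float, pd.DataFrame]

    def write(self, out_dir) -> None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        for name, table in self.tables.items():
            table.to_csv(out_dir / f"{name}.csv", index=False, float_format="%.6g")
        with open(out_dir / "manifest.json", "w") as fh:
            json.dump(self.manifest, fh, indent=1, sort_keys=True)
            fh.write("\n")
        with open(out_dir / "exclusions.json", "w") as fh:
            json.dump(self.exclusions, fh, indent=1, sort_keys=True)
            fh.write("\n")


def _preprocess_record(
    per_var: Mapping[str, VitalSignSeries],
    config: RunConfig,
    exclusions: list[dict],
    patient_id: str,
):
    """Per-variable preprocessing; returns residuals and raw (gap-handled) means."""
    residuals = {}
    means = {}
    for var, series in per_var.items():
        try:
            gapless, report = handle_gaps(series, max_fill_gap=config.max_fill_gap)
        except EmptySeriesError:
            exclusions.append(
                {"patient_id": patient_id, "variable": var, "reason": "series_all_missing"}
            )
            continue
        means[var] = float(np.mean(gapless.values))
        residual = preprocess_series(series, kernel_sd=config.kernel_sd_s,
                                     max_fill_gap=config.max_fill_gap)
        residuals[var] = residual
    return residuals, means


def run_pipeline(
    config: RunConfig,
    dataset: tuple[Sequence[PatientRecord], Mapping[str, Mapping[str, VitalSignSeries]]] | None = None,
) -> PipelineResult:
    """Execute the full analysis and return all report tables.

    ``dataset`` may be passed in memory; otherwise it is read from
    ``config.dataset_manifest`` or generated from ``config.generator`` with
    ``config.seed``.  Identical config and seed give identical results.
    """
    rng = np.random.default_rng(config.seed)

    if dataset is not None:
        records, store = dataset
    elif config.dataset_manifest:
        records, store = _io.read_dataset(config.dataset_manifest)
    else:
        logger.info("generating synthetic cohort (seed=%d)", config.seed)
        records, store = generate_cohort(config.generator, config.seed)

    n_input = len(records)
    records, exclusions = eligibility_filter(
        records, store, min_duration=config.min_duration_s
    )
    logger.info("eligibility: %d of %d records retained", len(records), n_input)

    # Per-record preprocessing (window-independent).
    residual_store = {}
    mean_store = {}
    for record in records:
        residuals, means = _preprocess_record(
            store.get(record.patient_id, {}), config, exclusions, record.patient_id
        )
        residual_store[record.patient_id] = residuals
        mean_store[record.patient_id] = means

    tables: dict[str, pd.DataFrame] = {}
    outcomes_by_window: dict[float, list[RecordOutcome]] = {}
    fits_by_window: dict[float, dict[int, inference.LogisticFit]] = {}
    anova_by_window: dict[float, pd.DataFrame] = {}
    counts_rows = []
    prop_tables = []
    ztest_rows = []
    welch_rows = []
    confusion_rows = []
    combined_rows = []

    for window_min in config.window_minutes:
        spec = WindowSpec(window_min=window_min)
        min_samples = 2 * spec.window_samples
        outcomes: list[RecordOutcome] = []
        for record in records:
            traces = {}
            for var, residual in residual_store[record.patient_id].items():
                if len(residual) < min_samples:
                    exclusions.append(
                        {
                            "patient_id": record.patient_id,
                            "variable": var,
                            "window_min": window_min,
                            "reason": "residual_shorter_than_two_windows",
                        }
                    )
                    continue
                traces[var] = compute_ews_trace(residual, spec)
            if not traces:
                continue
            outcomes.append(
                evaluate_record(
                    record, traces, alpha=config.alpha, alternative=config.mk_alternative
                )
            )
        outcomes_by_window[window_min] = outcomes
        by_id = {o.patient_id: o for o in outcomes}
        record_by_id = {r.patient_id: r for r in records}

        for case_cohort, control_cohort in config.cohort_pairs:
            cases = [record_by_id[o.patient_id] for o in outcomes if o.cohort == case_cohort]
            controls = [
                record_by_id[o.patient_id] for o in outcomes if o.cohort == control_cohort
            ]
            if not cases or not controls:
                logger.warning(
                    "window %g: cohort pair (%d, %d) empty, skipped",
                    window_min, case_cohort, control_cohort,
                )
                continue
            if config.stratify_age and (case_cohort, control_cohort) == (1, 2):
                controls = inference.stratify_match(
                    cases, controls, rng=rng, n_bins=config.age_bins
                )
            pair_outcomes = [by_id[r.patient_id] for r in cases] + [
                by_id[r.patient_id] for r in controls
            ]
            pair_label = f"{case_cohort}v{control_cohort}"

            # evaluable counts (Table-2 style)
            prop = inference.proportion_table(
                pair_outcomes, by_ward=config.ward_split
            )
            prop["window_min"] = window_min
            prop["pair"] = pair_label
            prop_tables.append(prop)
            for _, row in prop[
                (prop["indicator"] == "variance")
            ].iterrows():
                counts_rows.append(
                    {
                        "window_min": window_min,
                        "pair": pair_label,
                        "variable": row["variable"],
                        "ward": row["ward"],
                        "cohort": row["cohort"],
                        "n_evaluable": row["n_evaluable"],
                    }
                )

            # z-tests on proportions, per cell
            wards = (["PICU", "CICU", "NICU"] if config.ward_split else []) + ["Whole"]
            for ward in wards:
                for variable in VARIABLES:
                    for indicator in INDICATORS:
                        cell = prop[
                            (prop["ward"] == ward)
                            & (prop["variable"] == variable)
                            & (prop["indicator"] == indicator)
                        ]
                        c1 = cell[cell["cohort"] == case_cohort]
                        c2 = cell[cell["cohort"] == control_cohort]
                        if c1.empty or c2.empty or not (
                            c1["n_evaluable"].iat[0] and c2["n_evaluable"].iat[0]
                        ):
                            continue
                        z, p = inference.two_proportion_ztest(
                            int(c1["n_significant"].iat[0]), int(c1["n_evaluable"].iat[0]),
                            int(c2["n_significant"].iat[0]), int(c2["n_evaluable"].iat[0]),
                            alternative=config.ztest_alternative,
                        )
                        ztest_rows.append(
                            {
                                "window_min": window_min, "pair": pair_label,
                                "ward": ward, "variable": variable,
                                "indicator": indicator,
                                "prop_case": c1["proportion"].iat[0],
                                "prop_control": c2["proportion"].iat[0],
                                "z": z, "p": p,
                                "significant": p < config.alpha,
                            }
                        )

                        # Welch t-test on tau distributions for the same cell
                        tau_case = _cell_taus(pair_outcomes, case_cohort, ward, variable, indicator)
                        tau_ctrl = _cell_taus(pair_outcomes, control_cohort, ward, variable, indicator)
                        if len(tau_case) >= 2 and len(tau_ctrl) >= 2:
                            t, df, wp = inference.welch_ttest(
                                tau_case, tau_ctrl, alternative=config.welch_alternative
                            )
                            welch_rows.append(
                                {
                                    "window_min": window_min, "pair": pair_label,
                                    "ward": ward, "variable": variable,
                                    "indicator": indicator,
                                    "mean_case": float(np.mean(tau_case)),
                                    "se_case": float(np.std(tau_case, ddof=1) / np.sqrt(len(tau_case))),
                                    "mean_control": float(np.mean(tau_ctrl)),
                                    "se_control": float(np.std(tau_ctrl, ddof=1) / np.sqrt(len(tau_ctrl))),
                                    "t": t, "df": df, "p": wp,
                                    "significant": wp < config.alpha,
                                }
                            )

            # confusion metrics + positive-tau AUC per (variable, indicator)
            for variable in VARIABLES:
                for indicator in INDICATORS:
                    cm, metrics = _pair_confusion(
                        pair_outcomes, case_cohort, control_cohort, variable, indicator
                    )
                    taus, labels = _pair_taus(
                        pair_outcomes, case_cohort, variable, indicator
                    )
                    auc = np.nan
                    if len(set(labels)) == 2:
                        _, _, auc = inference.roc_auc_positive_tau(taus, labels)
                    confusion_rows.append(
                        {
                            "window_min": window_min, "pair": pair_label,
                            "variable": variable, "indicator": indicator,
                            "tp": cm.tp, "fp": cm.fp, "fn": cm.fn, "tn": cm.tn,
                            "ppv": metrics.ppv, "npv": metrics.npv,
                            "sensitivity": metrics.sensitivity,
                            "specificity": metrics.specificity,
                            "balanced_accuracy": metrics.balanced_accuracy,
                            "auc": auc,
                        }
                    )

            # combined strength of positive trends
            indicators_used = (
                INDICATORS if config.combined_tau_both_indicators else ("autocorrelation",)
            )
            scores, labels = [], []
            for o in pair_outcomes:
                taus = [
                    r.tau
                    for (v, ind), r in o.results.items()
                    if ind in indicators_used
                ]
                if taus:
                    scores.append(inference.combined_strength(taus))
                    labels.append(o.cohort == case_cohort)
            scores_arr = np.asarray(scores)
            labels_arr = np.asarray(labels)
            if labels_arr.any() and not labels_arr.all():
                t, df, p = inference.welch_ttest(
                    scores_arr[labels_arr], scores_arr[~labels_arr], alternative="greater"
                )
                _, _, combined_auc = inference.roc_auc_positive_tau(
                    scores_arr, labels_arr
                )
                combined_rows.append(
                    {
                        "window_min": window_min, "pair": pair_label,
                        "t": t, "df": df, "p": p, "auc": combined_auc,
                        "mean_case": float(scores_arr[labels_arr].mean()),
                        "mean_control": float(scores_arr[~labels_arr].mean()),
                    }
                )

            # logistic models, primary pair only
            if (case_cohort, control_cohort) == (1, 2):
                design = inference.build_design_table(pair_outcomes, means=mean_store)
                fits: dict[int, inference.LogisticFit] = {}
                for model_id in inference.MODEL_PREDICTORS:
                    try:
                        fits[model_id] = inference.fit_logistic(
                            model_id, design, weight_failure=config.weight_failure
                        )
                    except (ValueError, RuntimeError) as exc:
                        logger.warning("window %g model %d: %s", window_min, model_id, exc)
                fits_by_window[window_min] = fits
                anova_rows = []
                if 6 in fits:
                    full_rows = design.dropna(
                        subset=inference.MODEL_PREDICTORS[6]
                    )
                    for nested_id in (4, 5):
                        if nested_id not in fits:
                            continue
                        try:
                            nested = inference.fit_logistic(
                                nested_id, full_rows, weight_failure=config.weight_failure
                            )
                            full = inference.fit_logistic(
                                6, full_rows, weight_failure=config.weight_failure
                            )
                            dev, dfd, p = inference.anova_deviance(nested, full)
                            anova_rows.append(
                                {
                                    "window_min": window_min,
                                    "nested_model": nested_id, "full_model": 6,
                                    "deviance": dev, "df": dfd, "p": p,
                                }
                            )
                        except (ValueError, RuntimeError) as exc:
                            logger.warning("anova %d vs 6: %s", nested_id, exc)
                anova_by_window[window_min] = pd.DataFrame(anova_rows)

    tables["counts"] = pd.DataFrame(counts_rows)
    tables["proportions"] = (
        pd.concat(prop_tables, ignore_index=True) if prop_tables else pd.DataFrame()
    )
    tables["proportion_ztests"] = pd.DataFrame(ztest_rows)
    tables["tau_welch"] = pd.DataFrame(welch_rows)
    tables["confusion_metrics"] = pd.DataFrame(confusion_rows)
    tables["combined_strength"] = pd.DataFrame(combined_rows)
    logistic_rows = []
    for window_min, fits in fits_by_window.items():
        for model_id, fit in fits.items():
            for name, coef in fit.coefficients.iterrows():
                logistic_rows.append(
                    {
                        "window_min": window_min, "model": model_id,
                        "term": name, "estimate": coef["estimate"],
                        "se": coef["se"], "z": coef["z"], "p": coef["p"],
                        "n": fit.n, "aic": fit.aic,
                        "nagelkerke_r2": fit.nagelkerke_r2,
                        "deviance": fit.deviance,
                    }
                )
    tables["logistic_models"] = pd.DataFrame(logistic_rows)
    tables["anova"] = (
        pd.concat(anova_by_window.values(), ignore_index=True)
        if anova_by_window
        else pd.DataFrame()
    )

    manifest = {
        "config": _io._config_to_jsonable(config),
        "n_records_input": n_input,
        "n_records_eligible": len(records),
        "n_excluded": n_input - len(records),
        "n_exclusion_events": len(exclusions),
        "n_outcomes_per_window": {
            str(w): len(o) for w, o in outcomes_by_window.items()
        },
        "tables": sorted(tables),
    }
    return PipelineResult(
        config=config,
        manifest=manifest,
        exclusions=exclusions,
        outcomes=outcomes_by_window,
        tables=tables,
        logistic_fits=fits_by_window,
        anova=anova_by_window,
    )


def _cell_taus(outcomes, cohort, ward, variable, indicator):
    return np.array(
        [
            o.results[(variable, indicator)].tau
            for o in outcomes
            if o.cohort == cohort
            and (ward == "Whole" or o.ward == ward)
            and (variable, indicator) in o.results
        ]
    )


def _pair_confusion(outcomes, case_cohort, control_cohort, variable, indicator):
    tp = fp = fn = tn = 0
    for o in outcomes:
        res = o.results.get((variable, indicator))
        if res is None:
            continue
        if o.cohort == case_cohort:
            tp += res.significant_increase
            fn += not res.significant_increase
        elif o.cohort == control_cohort:
            fp += res.significant_increase
            tn += not res.significant_increase
    cm = inference.ConfusionMatrix(tp=tp, fp=fp, fn=fn, tn=tn)
    return cm, inference.metrics_from_confusion(cm)


def _pair_taus(outcomes, case_cohort, variable, indicator):
    taus, labels = [], []
    for o in outcomes:
        res = o.results.get((variable, indicator))
        if res is None:
            continue
        taus.append(res.tau)
        labels.append(o.cohort == case_cohort)
    return np.asarray(taus), np.asarray(labels)
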