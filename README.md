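# icuews

Early-warning-signal (EWS) analysis of post-extubation vital-sign time
series in paediatric intensive care.

When a dynamical system approaches a fold bifurcation it exhibits
*critical slowing down* (CSD): perturbations decay ever more slowly, so the
variance and autocorrelation of its fluctuations rise.  If a child who
fails extubation (needs re-intubation within 48 h) is approaching such a
physiological tipping point, their heart rate (HR), respiratory rate (RR)
and mean blood pressure (ABP) should show rising sliding-window variance
and lag-1 autocorrelation between extubation and re-intubation.  This
package implements that analysis end to end, for researchers studying EWS
in bedside monitoring data:

- **Model.** Fluctuations around a slowly varying baseline follow the
  linearized dynamics `dx/dt = -λx + σε` — an Ornstein–Uhlenbeck process
  with stationary variance `σ²/(2λ)` and autocorrelation
  `ACF(τ) = exp(-λτ)`.  Approach to the bifurcation means `λ → 0`, so the
  variance diverges and the lag-1 autocorrelation tends to 1.
- **Indicators.** On 5-s-sampled residual series, unbiased sample variance
  `σ²_t` and lag-1 autocorrelation `r1_t` are computed on 60-min windows
  slid forward by 1 min (15- and 30-min windows as sensitivity analyses).
- **Trend tests.** Each indicator trace is tested for a significant
  *increase* with the Hamed–Rao modified Mann–Kendall test (Kendall τ with
  a serial-correlation-corrected variance of S); the up-to-six tests of a
  record form one Holm–Bonferroni family at α = 0.05.
- **Cohort inference.** Proportions of significant increases with
  two-proportion z-tests, Welch t-tests on the τ distributions, confusion
  matrices (PPV, NPV, sensitivity, specificity, balanced accuracy),
  positive-τ ROC/AUC, a combined positive-τ strength score, six weighted
  (10:1) logistic regression models with Nagelkerke R² and AIC, and
  deviance ANOVA between nested models.
- **Synthetic cohorts.** Because no such bedside dataset is public, a
  first-class generator produces labelled cohorts: failure records ramp λ
  toward zero ahead of the endpoint, controls stay stationary, with
  baselines, missing-data gaps, matched interval durations
  (pseudo-re-intubation sampling) and ward/age/sex mixtures.

## Worked example

```python
import numpy as np
from icuews import CohortConfig, RunConfig, run_pipeline

config = RunConfig(seed=42, generator=CohortConfig(n_cohort1=30, n_cohort2=120))
result = run_pipeline(config)

cm = result.tables["confusion_metrics"]
hr = cm[(cm.variable == "HR") & (cm.indicator == "autocorrelation")].iloc[0]
print(f"HR lag-1 AC: TP={hr.tp} FP={hr.fp} FN={hr.fn} TN={hr.tn}")
print(f"sensitivity={hr.sensitivity:.3f} specificity={hr.specificity:.3f} "
      f"AccB={hr.balanced_accuracy:.3f} AUC={hr.auc:.3f}")

zt = result.tables["proportion_ztests"]
cell = zt[(zt.ward == "Whole") & (zt.variable == "HR")
          & (zt.indicator == "autocorrelation")].iloc[0]
print(f"proportions: cohort1={cell.prop_case:.3f} cohort2={cell.prop_control:.3f} "
      f"z={cell.z:.2f} p={cell.p:.2g}")

an = result.tables["anova"].iloc[0]
print(f"ANOVA model 4 vs 6: deviance={an.deviance:.2f} p={an.p:.2g}")
```

prints

```
HR lag-1 AC: TP=17 FP=6 FN=13 TN=24
sensitivity=0.567 specificity=0.800 AccB=0.683 AUC=0.800
proportions: cohort1=0.567 cohort2=0.200 z=2.92 p=0.0017
ANOVA model 4 vs 6: deviance=27.60 p=4.4e-06
```

Reading this: 30 failure records (cohort 1) and 120 controls (cohort 2)
were simulated, preprocessed and tested.  17 of the 30 failures showed a
Holm-significant increase in heart-rate lag-1 autocorrelation before their
endpoint (sensitivity 0.567) against a 20% false-alarm rate in controls;
the cohort difference in those proportions is significant (one-sided
z-test, p ≈ 0.002), and adding the Kendall-τ predictors to a vital-sign-
means-only logistic model improves the fit (deviance ANOVA).  Synthetic
cohorts carry a deliberately clear CSD signal, so discrimination here is
stronger than one should expect from clinical data.

The same run is available from the shell:

```sh
icuews all --seed 42 -o out/           # simulate + full report
icuews simulate --seed 1 -o data/      # dataset only
icuews report -d data/manifest.json -o report/
```

with stage-wise subcommands (`preprocess`, `ews`, `trend`) for
intermediate artifacts.  All outputs are plain CSV/JSON and are
byte-reproducible given the same config and seed.

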