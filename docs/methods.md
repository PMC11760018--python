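# Methods

## Model

Residual fluctuations of each vital sign about its slowly varying baseline
are modelled as the linearization of the physiological state around a
stable equilibrium,

    dx/dt = -λ x + σ ε,        λ > 0,

an Ornstein–Uhlenbeck (OU) process with white noise ε.  Its stationary
moments are `Var(x) = σ²/(2λ)` and `ACF(τ) = exp(-λτ)`.  Approach to a
fold bifurcation corresponds to the decay rate λ (the magnitude of the
dominant eigenvalue) shrinking toward zero: the variance diverges and the
lag-1 autocorrelation tends to 1 — critical slowing down (CSD).  The
literature sometimes writes the linearization with `+λx`; that form is
unstable for λ > 0 and inconsistent with the stationary moments above, so
the decay-rate convention is used throughout and "λ → 0" is read as the
decay rate approaching zero.

Simulation uses the exact OU discretization
`x_{k+1} = x_k e^{-λΔt} + N(0, σ²(1 - e^{-2λΔt})/(2λ))`, which is unbiased
at any step size (the 5-s monitor grid is coarse relative to fast decay
rates, where Euler–Maruyama would distort the moments).  Time-varying λ is
treated as piecewise-constant per step, evaluated blockwise with a
rescaled cumulative sum so the running decay product never underflows.
Initial states are drawn from the stationary law.

## Analysis pipeline

1. **Eligibility.** Records whose extubation-to-endpoint interval is
   shorter than 120 min are excluded (inclusive boundary: exactly 120 min
   is retained), so the 60-min window never exceeds half the record.
2. **Gap handling.** Missing runs of ≤ 10 samples are filled with the mean
   of the two flanking observations; longer runs are spliced out and the
   flanks concatenated on a contiguous grid (splice positions kept as
   provenance; windows spanning a splice are retained).  Leading/trailing
   missing runs are trimmed.
3. **Detrending.** A Gaussian-kernel smooth (SD 10 min, reflective
   boundary) estimates the long-term baseline; subtracting it leaves the
   residual.  The kernel SD sits well below the 60-min analysis window so
   the removed component is long-term relative to what the indicators
   measure; a single pass is applied (a second pass removes essentially
   nothing, as the idempotence test verifies).
4. **Outlier clipping.** Residuals outside mean ± 3 SD are replaced by the
   mean; mean and SD are computed once per record on the input residual,
   not re-estimated after replacement and not per window.
5. **Indicators.** Unbiased sample variance (denominator n − 1) and lag-1
   autocorrelation about the window mean, on left-aligned windows of
   60 min (primary; 15/30 min as sensitivity settings) advanced by 1 min,
   timestamped by window start.  Constant windows yield an undefined
   autocorrelation and are skipped downstream.
6. **Trend tests.** Mann–Kendall S and Kendall τ (tau-a; ties in
   continuous indicator traces have measure zero, but the tie term is
   subtracted from Var₀(S) regardless) against time order.  The Hamed–Rao
   correction multiplies Var₀(S) by
   `1 + 2/(n(n-1)(n-2)) Σᵢ (n-i)(n-i-1)(n-i-2) ρ_s(i)`, where ρ_s(i) is
   the lag-i autocorrelation of the ranks of the Sen-slope-detrended
   trace, summed over lags whose autocorrelation exceeds the two-sided 95%
   normal band ±z₀.₉₇₅/√n.  The factor is floored at 1, so the corrected
   test is never anti-conservative relative to the classical one; when the
   detrended trace is exactly constant (a noiseless trend) the correction
   is skipped, since rank structure there is a tie-breaking artifact.
   Traces shorter than 10 points fall back to the uncorrected test with a
   warning.  p-values are one-sided for an increase (the alternative
   hypothesis is rising indicators; a config switch provides two-sided).
7. **Per-record correction.** The up-to-six p-values of a record (three
   variables × two indicators) form one Holm–Bonferroni family at
   α = 0.05; a *significant increase* additionally requires τ > 0.
8. **Cohort inference.** Controls are age-matched to cases by binned
   subsampling (8 uniform bins by default; sex is left unmatched, ward is
   handled by subgroup analysis).  Proportions of significant increases
   are compared with a pooled two-proportion z-test (one-sided, case
   cohort greater); τ distributions with Welch's t-test
   (Welch–Satterthwaite df; two-sided for the summary tables, one-sided
   available).  Classification treats "significant increase" as the
   positive prediction and extubation failure as the positive class.  The
   ROC sweeps the τ threshold with all τ ≤ 0 mapped to a common sentinel
   below every threshold (only positive trends count as evidence); with no
   positive τ at all the classifier is uninformative and AUC is 0.5 by
   convention.  The combined strength score is Σ max(τ, 0) over the
   record's available coefficients (both indicators by default; a switch
   restricts it to autocorrelation only).
9. **Logistic models.** Six weighted maximum-likelihood fits (failure
   weight 10, success weight 1, as frequency weights in the
   log-likelihood): per-variable τ pairs (models 1–3), all six τ (4),
   vital-sign means only (5), all nine predictors (6).  Rows are
   complete-case per model, so models 4–6 fit on fewer records; n is
   reported unweighted.  Nagelkerke R² = [1 − (L0/L1)^(2/n)] / [1 −
   L0^(2/n)] uses the weighted intercept-only likelihood on the same rows
   and the unweighted n.  Complete separation is reported as a convergence
   failure (non-finite or exploding standard errors, or non-intercept
   slopes beyond ±50), never silently clipped.  Deviance ANOVA between
   nested fits (on identical rows and weights) uses the χ² reference with
   df equal to the parameter-count difference.

## Synthetic cohort generator

The generator emulates the statistical structure of the bedside data the
analysis was designed for — not cardio-respiratory physiology:

- 5-s sampling; per-record interval durations truncated-lognormal
  (median 6 h, log-SD 0.7, support [2 h, 48 h]); control endpoint times
  drawn by resampling the failure cohort's durations
  (pseudo-re-intubation), so analyzed-interval lengths match across
  cohorts by construction.
- Baselines: HR 120 BPM, RR 30 BrPM, ABP 60 mmHg with a slow sinusoidal
  drift (amplitudes 5/2/3 units, period 2 h, random phase) to exercise the
  detrending stage.  These are plausibility defaults, not clinical claims.
- Residual noise amplitudes σ (HR 1.5, RR 0.9, ABP 1.1 units·s^-1/2) give
  stationary SDs of roughly 2–3.5 signal units at the control decay rate.
- Decay rates: controls are stationary at λ = 0.1 s⁻¹ (lag-1 ACF 0.61 on
  the 5-s grid).  Failure records ramp λ linearly down to a terminal value
  reached exactly at the endpoint; the terminal value is drawn
  log-uniformly from [0.005, 0.1] s⁻¹ and the ramp onset uniformly from
  20–90% of the record.  This heterogeneity reflects that re-intubation is
  a clinical judgement made at varying proximity to the underlying
  transition, and it is what keeps the synthetic cohorts from being
  perfectly separable (an early homogeneous-ramp design produced complete
  separation in every logistic model, which no clinical cohort would).
- Missingness: per-sample gap-start rates 2×10⁻³ (short, geometric mean
  4 samples, capped at 10) and 3×10⁻⁴ (long, mean 30, minimum 11), so
  both the fill and the splice branch of gap handling are exercised.
- Ward mix 25/62/13% (PICU/CICU/NICU), per-variable availability HR 100%,
  RR 84%, ABP 70%, mirroring the unequal per-variable counts such monitor
  datasets show; ages lognormal (median 1 y, capped at 18 y).

All randomness flows from a single seed; regeneration is byte-identical.

What passing tests on these cohorts do *not* show: that CSD of this
strength, or CSD at all, is present in real post-extubation physiology.
The generator realizes the hypothesis the analysis is built to test; real
data add confounders (interventions, drug effects, fluid shifts,
waveform-derivation artifacts) that this model deliberately omits.

## Calibration caveat

The indicator traces are computed on windows that overlap by 59/60, so
adjacent trace points share almost all their data and the trace is
strongly serially dependent *by construction*, whatever the underlying
dynamics.  The Hamed–Rao correction — whose rank autocorrelation must be
estimated from the 60–300-point trace itself — removes only part of this:
on iid traces the test is calibrated (measured rejection ≈ 0.05 at
α = 0.05), and it is never more false-positive-prone than the uncorrected
test, but on stationary *records* the family-wise rate of significant-
increase calls measured by the test suite is far above α.  Control-cohort
proportions should therefore be read as an empirical false-alarm rate of
the whole procedure, not as a calibrated error level; cohort comparisons
(z-tests, t-tests, AUC) remain meaningful because both cohorts share the
same inflation.

## Numerical and design choices

- Window of m = window·60/5 samples, half-open [t, t+m) in samples,
  left-aligned, trace timestamped by window start (the timestamp
  convention is irrelevant downstream: Mann–Kendall is rank-based in time
  order).
- Continuity correction in the MK z statistic: z = (S∓1)/√Var*(S) for
  S ≷ 0, z = 0 at S = 0; constant traces return τ = 0, p = 1.
- Holm families are per record (the tests actually available for that
  record), not per cohort.
- Age stratification: binned subsampling sized by the scarcest bin; bins
  with cases but no controls emit a warning and contribute nothing.
- Degenerate proportions (pooled 0 or 1) give z = 0, p = 1; 0/0 metric
  ratios are reported as NaN, never as 0.
- Within-record times are seconds since extubation; indices are 0-based
  internally.

## Limitations

- The Welch t-test on τ summaries treats per-record τ values as
  exchangeable draws; records differ in trace length, so their τ values
  have unequal sampling variances.
- The Hamed–Rao calibration gap above is inherent to trend-testing
  overlapping-window EWS traces; surrogate or block-bootstrap significance
  would be the robust alternative and is out of scope here.
- The generator's missingness is unstructured (random gap starts), while
  real monitor dropouts cluster around care events.
- Eligibility, gap handling and windowing follow one fixed convention
  each; the config exposes window length, kernel SD, minimum duration,
  test sidedness and cohort pairs, but not alternative splice or
  clipping rules.
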