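"""Published summary numbers from a paediatric-ICU extubation study.

The real bedside dataset behind this analysis design is not publicly
deposited, but the study's printed summary tables are.  They are recorded
here as inputs for worked examples and cross-checks: cohort sizes, the
per-variable evaluable record counts by ward, one confusion-matrix row, and
one pair of Kendall-tau summary statistics.

Cohorts: 1 = failed extubation, re-intubated, survived; 2 = successful
extubation (controls); 3 = not re-intubated, died; 4 = re-intubated, died.
"""

from __future__ import annotations

__all__ = [
    "COHORT_SIZES",
    "EVALUABLE_COUNTS",
    "HR_AUTOCORR_CONFUSION",
    "HR_AUTOCORR_TAU_SUMMARY",
    "failure_rate",
]

#: Cohort sizes prior to preprocessing.
COHORT_SIZES = {1: 184, 2: 2479, 3: 333, 4: 38}

#: Evaluable record counts per (variable, ward, cohort) after preprocessing.
EVALUABLE_COUNTS = {
    "HR": {
        "PICU": {1: 47, 2: 354, 3: 32, 4: 12},
        "CICU": {1: 40, 2: 936, 3: 28, 4: 4},
        "NICU": {1: 14, 2: 185, 3: 13, 4: 2},
        "Whole": {1: 101, 2: 1475, 3: 73, 4: 18},
    },
    "RR": {
        "PICU": {1: 37, 2: 305, 3: 26, 4: 12},
        "CICU": {1: 33, 2: 771, 3: 21, 4: 4},
        "NICU": {1: 11, 2: 164, 3: 9, 4: 1},
        "Whole": {1: 81, 2: 1240, 3: 56, 4: 17},
    },
    "ABP": {
        "PICU": {1: 21, 2: 164, 3: 22, 4: 7},
        "CICU": {1: 34, 2: 846, 3: 20, 4: 4},
        "NICU": {1: 4, 2: 23, 3: 3, 4: 1},
        "Whole": {1: 59, 2: 1033, 3: 45, 4: 12},
    },
}

#: Published confusion counts for the heart-rate lag-1-autocorrelation
#: indicator, cohort 1 vs cohort 2 (TP, FP, FN, TN).
HR_AUTOCORR_CONFUSION = {"tp": 24, "fp": 253, "fn": 77, "tn": 1222}

#: Published whole-cohort Kendall-tau summaries for the heart-rate
#: autocorrelation indicator: (mean, standard error, n) per cohort.
HR_AUTOCORR_TAU_SUMMARY = {1: (0.069, 0.036, 101), 2: (-0.027, 0.009, 1475)}


def failure_rate(n_failures: int, n_controls: int) -> float:
    """Extubation-failure rate among survivors: failures / (failures + controls)."""
    return n_failures / (n_failures + n_controls)
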