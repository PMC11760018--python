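"""Trend significance testing for early-warning-signal traces.

Each record yields up to six indicator traces (three vital signs x two
indicators).  For each trace we compute the Mann-Kendall statistic S and
Kendall tau against time order, then test for a significant *increase* with
the Hamed-Rao modified Mann-Kendall test, which inflates Var(S) to account
for the serial correlation that overlapping windows induce in the trace.
The up-to-six one-sided p-values of a record form one Holm-Bonferroni family
(alpha = 0.05 by default); a trace counts as a significant increase only if
its Holm-corrected test rejects AND tau > 0.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy import stats

from .ews import EWSTrace
from .synthetic import InvalidParameterError, PatientRecord

__all__ = [
    "TrendResult",
    "RecordOutcome",
    "kendall_s_tau",
    "hamed_rao_mk_test",
    "holm_bonferroni",
    "evaluate_record",
    "INDICATORS",
]

INDICATORS = ("variance", "autocorrelation")


@dataclass
class TrendResult:
    """Outcome of one modified Mann-Kendall test on one indicator trace."""

    variable: str
    indicator: str
    n: int
    tau: float
    s_statistic: float
    var_s: float
    z: float
    p: float
    significant_increase: bool = False


@dataclass
class RecordOutcome:
    """All trend tests of one record, Holm-corrected within the record."""

    patient_id: str
    cohort: int
    ward: str
    results: dict[tuple[str, str], TrendResult] = field(default_factory=dict)

    @property
    def family_size(self) -> int:
        return len(self.results)


def kendall_s_tau(values: Sequence[float]) -> tuple[int, float]:
    """Mann-Kendall S and Kendall tau of a trace against time order.

    S = sum_{i<j} sign(x_j - x_i); tau = S / (n(n-1)/2) (tau-a; ties in the
    continuous indicator traces have measure zero).
    """
    x = np.asarray(values, dtype=float)
    n = len(x)
    if n < 2:
        raise InvalidParameterError("trend test needs at least 2 values")
    s = int(sum(np.sign(x[i + 1 :] - x[i]).sum() for i in range(n - 1)))
    tau = s / (n * (n - 1) / 2.0)
    return s, tau


def _ties_term(x: np.ndarray) -> float:
    _, counts = np.unique(x, return_counts=True)
    tied = counts[counts > 1]
    return float(np.sum(tied * (tied - 1) * (2 * tied + 5)) / 18.0)


def _acf(x: np.ndarray, nlags: int) -> np.ndarray:
    """Biased sample autocorrelation (denominator n), lags 0..nlags."""
    x = x - x.mean()
    n = len(x)
    full = np.correlate(x, x, mode="full")[n - 1 :]
    return full[: nlags + 1] / full[0]


def hamed_rao_mk_test(
    values: Sequence[float],
    alpha: float = 0.05,
    alternative: str = "increase",
    corrected: bool = True,
    variable: str = "",
    indicator: str = "",
) -> TrendResult:
    """Modified Mann-Kendall test with the Hamed-Rao variance correction.

    The correction multiplies the null variance of S by

        n/n* = 1 + 2 / (n(n-1)(n-2)) * sum_i (n-i)(n-i-1)(n-i-2) rho_s(i)

    where rho_s(i) is the lag-i autocorrelation of the ranks of the
    Sen-slope-detrended trace, summed over lags 1..n-1 whose autocorrelation
    falls outside the two-sided 95% normal band +/- z_{0.975}/sqrt(n).  The
    factor is floored at 1 so the corrected test is never anti-conservative
    relative to the classical test.  z uses the standard continuity
    correction; ``alternative`` is one of ``increase`` (one-sided, the
    default: the alternative hypothesis is a rising indicator), ``decrease``
    or ``two-sided``.

    Traces shorter than 10 points fall back to the uncorrected test with a
    warning; NaN values (skipped windows) are dropped first.
    """
    x = np.asarray(values, dtype=float)
    x = x[~np.isnan(x)]
    n = len(x)
    if n < 2:
        raise InvalidParameterError("trend test needs at least 2 finite values")

    s, tau = kendall_s_tau(x)
    var0 = n * (n - 1) * (2 * n + 5) / 18.0 - _ties_term(x)

    if var0 <= 0:  # constant trace: no evidence either way
        return TrendResult(variable, indicator, n, 0.0, float(s), 0.0, 0.0, 1.0)

    factor = 1.0
    detrended = None
    if corrected:
        if n < 10:
            warnings.warn(
                f"trace of length {n} < 10: Hamed-Rao correction skipped",
                stacklevel=2,
            )
        else:
            slope = stats.theilslopes(x)[0]
            detrended = x - slope * np.arange(n)
            if np.allclose(detrended, detrended[0]):
                # A pure trend detrends to a constant; its ranks carry no
                # autocorrelation information (any structure would be a
                # tie-breaking artifact), so no correction is applied.
                detrended = None
        if detrended is not None:
            ranks = stats.rankdata(detrended, method="ordinal").astype(float)
            rho = _acf(ranks, nlags=n - 1)
            band = stats.norm.ppf(1.0 - 0.05 / 2.0) / np.sqrt(n)
            lags = np.arange(1, n - 1)  # (n-i-2) factor vanishes beyond n-3
            significant = np.abs(rho[lags]) > band
            sni = np.sum(
                (n - lags[significant])
                * (n - lags[significant] - 1)
                * (n - lags[significant] - 2)
                * rho[lags[significant]]
            )
            factor = 1.0 + 2.0 / (n * (n - 1) * (n - 2)) * float(sni)
            factor = max(factor, 1.0)

    var_s = var0 * factor
    if s > 0:
        z = (s - 1) / np.sqrt(var_s)
    elif s < 0:
        z = (s + 1) / np.sqrt(var_s)
    else:
        z = 0.0

    if alternative == "increase":
        p = float(stats.norm.sf(z))
    elif alternative == "decrease":
        p = float(stats.norm.cdf(z))
    elif alternative == "two-sided":
        p = float(2.0 * stats.norm.sf(abs(z)))
    else:
        raise InvalidParameterError(f"unknown alternative {alternative!r}")

    return TrendResult(variable, indicator, n, tau, float(s), float(var_s), float(z), p)


def holm_bonferroni(p_values: Sequence[float], alpha: float = 0.05) -> np.ndarray:
    """Holm step-down rejection flags, returned in the input order.

    Sort the m p-values ascending and reject p_(i) while
    p_(i) <= alpha / (m - i + 1), stopping at the first failure; this
    controls the family-wise error rate at alpha.
    """
    p = np.asarray(p_values, dtype=float)
    if np.any((p < 0) | (p > 1)):
        raise InvalidParameterError("p-values must lie in [0, 1]")
    m = len(p)
    reject = np.zeros(m, dtype=bool)
    if m == 0:
        return reject
    order = np.argsort(p, kind="stable")
    for rank, idx in enumerate(order):
        if p[idx] <= alpha / (m - rank):
            reject[idx] = True
        else:
            break
    return reject


def evaluate_record(
    record: PatientRecord,
    traces: Mapping[str, EWSTrace],
    alpha: float = 0.05,
    alternative: str = "increase",
) -> RecordOutcome:
    """Run all available trend tests for one record and Holm-correct them.

    Each available variable contributes two tests (variance and lag-1
    autocorrelation traces), giving a family of at most six p-values.  A
    test is flagged as a significant increase when its Holm-corrected
    hypothesis rejects and its tau is positive.
    """
    outcome = RecordOutcome(
        patient_id=record.patient_id, cohort=record.cohort, ward=record.ward
    )
    keys: list[tuple[str, str]] = []
    for variable, trace in traces.items():
        for indicator, series in (
            ("variance", trace.variance),
            ("autocorrelation", trace.lag1_ac),
        ):
            finite = series[~np.isnan(series)]
            if len(finite) < 2:
                continue
            result = hamed_rao_mk_test(
                finite, alpha=alpha, alternative=alternative,
                variable=variable, indicator=indicator,
            )
            outcome.results[(variable, indicator)] = result
            keys.append((variable, indicator))

    if keys:
        rejections = holm_bonferroni([outcome.results[k].p for k in keys], alpha=alpha)
        for key, rej in zip(keys, rejections):
            res = outcome.results[key]
            res.significant_increase = bool(rej) and res.tau > 0
    return outcome
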