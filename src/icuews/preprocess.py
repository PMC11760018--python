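"""Preprocessing of raw vital-sign series into residual series.

Three steps, in order:

1. gap handling — short gaps (<= 10 samples) are filled with the mean of the
   two flanking observations; longer gaps are spliced out and the flanks
   concatenated on a contiguous time grid;
2. Gaussian detrending — a Gaussian-kernel smooth estimates the long-term
   baseline, which is subtracted to leave the residual fluctuations that the
   early-warning indicators are computed on;
3. outlier clipping — residuals outside mean +/- 3 SD are replaced by the
   mean (computed once on the input, not iterated).

Records whose analyzed interval is shorter than twice the indicator window
(120 min for the primary 60-min window) are excluded so that the sliding
window never exceeds half the record.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy.ndimage import gaussian_filter1d

from .synthetic import InvalidParameterError, PatientRecord, VitalSignSeries

__all__ = [
    "GapReport",
    "ResidualSeries",
    "EmptySeriesError",
    "handle_gaps",
    "detrend_gaussian",
    "clip_outliers",
    "preprocess_series",
    "eligibility_filter",
]

DEFAULT_KERNEL_SD_S = 600.0  # 10 min, well below the 60-min analysis window
DEFAULT_MIN_DURATION_S = 7200.0  # 120 min


class EmptySeriesError(ValueError):
    """Raised when gap handling leaves no usable samples."""


@dataclass
class GapReport:
    """Provenance of gap handling for one series."""

    filled_gaps: int = 0
    filled_samples: int = 0
    spliced_gaps: int = 0
    spliced_samples: int = 0
    trimmed_samples: int = 0
    splice_points: list[int] = field(default_factory=list)  # output sample index


@dataclass
class ResidualSeries:
    """Gap-free residual series plus preprocessing provenance."""

    variable: str
    times: np.ndarray
    values: np.ndarray
    gap_report: GapReport = field(default_factory=GapReport)
    clipped_outliers: int = 0

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if np.isnan(self.values).any():
            raise InvalidParameterError("residual series must be gap-free")

    def __len__(self) -> int:
        return len(self.values)

    @property
    def dt(self) -> float:
        return float(self.times[1] - self.times[0])


def _missing_runs(mask: np.ndarray) -> list[tuple[int, int]]:
    """Half-open [start, stop) runs of True in ``mask``."""
    padded = np.diff(np.concatenate(([0], mask.astype(np.int8), [0])))
    starts = np.flatnonzero(padded == 1)
    stops = np.flatnonzero(padded == -1)
    return list(zip(starts, stops))


def handle_gaps(
    series: VitalSignSeries, max_fill_gap: int = 10
) -> tuple[VitalSignSeries, GapReport]:
    """Fill short gaps and splice out long ones.

    Gaps of at most ``max_fill_gap`` samples are replaced by the mean of the
    two observations flanking the gap; longer gaps are deleted and the
    flanks concatenated, so the record shortens.  Leading and trailing
    missing runs (no flank on one side) are trimmed.  Output times are
    re-indexed to a contiguous grid starting at the original start time;
    splice positions are recorded in the report.
    """
    values = series.values.copy()
    mask = np.isnan(values)
    report = GapReport()
    if mask.all():
        raise EmptySeriesError(f"{series.variable}: series is entirely missing")

    keep = np.ones(len(values), dtype=bool)
    for start, stop in _missing_runs(mask):
        length = stop - start
        if start == 0 or stop == len(values):
            keep[start:stop] = False
            report.trimmed_samples += int(length)
        elif length <= max_fill_gap:
            values[start:stop] = 0.5 * (values[start - 1] + values[stop])
            report.filled_gaps += 1
            report.filled_samples += int(length)
        else:
            keep[start:stop] = False
            report.spliced_gaps += 1
            report.spliced_samples += int(length)

    # Output sample index of each splice (junction between former flanks).
    kept_cum = np.cumsum(keep)
    for start, stop in _missing_runs(~keep):
        if start > 0 and stop < len(values):
            report.splice_points.append(int(kept_cum[start - 1]))

    out_values = values[keep]
    if len(out_values) < 2:
        raise EmptySeriesError(f"{series.variable}: fewer than 2 samples after gap handling")
    out_times = series.times[0] + np.arange(len(out_values)) * series.dt
    out = VitalSignSeries(variable=series.variable, times=out_times, values=out_values)
    return out, report


def detrend_gaussian(
    series: VitalSignSeries, kernel_sd: float = DEFAULT_KERNEL_SD_S
) -> ResidualSeries:
    """Subtract a Gaussian-kernel smooth (reflective boundary) from the series.

    ``kernel_sd`` is the kernel standard deviation in seconds; the default
    (10 min) sits well below the 60-min indicator window, so the removed
    component is long-term relative to the scales the indicators measure.
    """
    if not kernel_sd > 0:
        raise InvalidParameterError("kernel_sd must be > 0")
    if np.isnan(series.values).any():
        raise InvalidParameterError("detrending requires a gap-free series")
    smoothed = gaussian_filter1d(series.values, sigma=kernel_sd / series.dt, mode="reflect")
    return ResidualSeries(
        variable=series.variable, times=series.times, values=series.values - smoothed
    )


def clip_outliers(series: ResidualSeries) -> ResidualSeries:
    """Replace residuals outside mean +/- 3 SD with the mean.

    The mean and SD are computed once on the input series (no re-estimation
    after replacement).  A constant series (SD 0) passes through unchanged.
    """
    values = series.values
    if len(values) == 0:
        raise InvalidParameterError("empty residual series")
    mu = float(values.mean())
    sd = float(values.std(ddof=0))
    out = values.copy()
    clipped = 0
    if sd > 0:
        mask = np.abs(values - mu) > 3.0 * sd
        out[mask] = mu
        clipped = int(mask.sum())
    return ResidualSeries(
        variable=series.variable,
        times=series.times,
        values=out,
        gap_report=series.gap_report,
        clipped_outliers=series.clipped_outliers + clipped,
    )


def preprocess_series(
    series: VitalSignSeries,
    kernel_sd: float = DEFAULT_KERNEL_SD_S,
    max_fill_gap: int = 10,
) -> ResidualSeries:
    """Full per-series pipeline: gap handling, detrending, outlier clipping."""
    gapless, report = handle_gaps(series, max_fill_gap=max_fill_gap)
    residual = detrend_gaussian(gapless, kernel_sd=kernel_sd)
    residual.gap_report = report
    return clip_outliers(residual)


def eligibility_filter(
    records: Sequence[PatientRecord],
    series_store: Mapping[str, Mapping[str, VitalSignSeries]] | None = None,
    min_duration: float = DEFAULT_MIN_DURATION_S,
) -> tuple[list[PatientRecord], list[dict]]:
    """Drop records whose analyzed interval is shorter than ``min_duration``.

    The boundary is inclusive: an interval of exactly ``min_duration``
    (120 min by default) is retained, intervals strictly shorter are
    removed.  Records with no series at all are also dropped.  Returns the
    retained records and a structured exclusion log.
    """
    retained: list[PatientRecord] = []
    exclusions: list[dict] = []
    for record in records:
        if record.duration < min_duration:
            exclusions.append(
                {
                    "patient_id": record.patient_id,
                    "cohort": record.cohort,
                    "reason": "duration_below_minimum",
                    "duration_s": record.duration,
                }
            )
            continue
        if series_store is not None and not series_store.get(record.patient_id):
            exclusions.append(
                {
                    "patient_id": record.patient_id,
                    "cohort": record.cohort,
                    "reason": "no_series_available",
                    "duration_s": record.duration,
                }
            )
            continue
        retained.append(record)
    return retained, exclusions
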