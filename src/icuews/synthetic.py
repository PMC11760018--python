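"""Synthetic cohorts of post-extubation vital-sign records.

The generator emulates the statistical structure of bedside monitor data
around an extubation episode: each vital sign is a slowly varying baseline
plus a residual that follows the linearized dynamics near a stable
equilibrium,

    dx/dt = -lam * x + sigma * eps,

an Ornstein-Uhlenbeck (OU) process with stationary variance sigma^2/(2*lam)
and autocorrelation exp(-lam*tau).  Critical slowing down ahead of a fold
bifurcation corresponds to the decay rate ``lam`` ramping toward zero, which
inflates both the variance and the lag-1 autocorrelation of the residual.
Records in the failure cohort are generated with such a ramp terminating at
the re-intubation time; control records use a stationary (constant ``lam``)
residual.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np

__all__ = [
    "OUParams",
    "RampSchedule",
    "PatientRecord",
    "VitalSignSeries",
    "BaselineSpec",
    "GapSpec",
    "CohortConfig",
    "closed_form_ou_moments",
    "simulate_ou",
    "simulate_record",
    "sample_pseudo_duration",
    "generate_cohort",
    "generate_cohort_dataset",
]

SAMPLE_INTERVAL_S = 5.0

WARDS = ("PICU", "CICU", "NICU")
SEXES = ("M", "F", "Unknown")
VARIABLES = ("HR", "RR", "ABP")

#: Units of the supported monitor variables.
VARIABLE_UNITS = {"HR": "BPM", "RR": "BrPM", "ABP": "mmHg", "SpO2": "%"}


class InvalidParameterError(ValueError):
    """Raised for physically meaningless model parameters."""


@dataclass(frozen=True)
class OUParams:
    """Parameters of the stationary OU residual model.

    Parameters
    ----------
    lam
        Decay rate (magnitude of the stable eigenvalue), 1/s.  Must be > 0;
        the stationary variance sigma^2/(2*lam) diverges as lam -> 0.
    sigma
        White-noise amplitude, signal-units * s^(-1/2).
    dt
        Sampling/integration step in seconds (monitor grid, default 5 s).
    """

    lam: float
    sigma: float
    dt: float = SAMPLE_INTERVAL_S

    def __post_init__(self) -> None:
        if not self.lam > 0:
            raise InvalidParameterError(f"lam must be > 0, got {self.lam}")
        if self.sigma < 0:
            raise InvalidParameterError(f"sigma must be >= 0, got {self.sigma}")
        if not self.dt > 0:
            raise InvalidParameterError(f"dt must be > 0, got {self.dt}")


@dataclass(frozen=True)
class RampSchedule:
    """Time course of the residual decay rate over one record.

    ``shape='constant'`` keeps ``lam_start`` throughout (stationary control
    dynamics); ``shape='linear'`` interpolates linearly in time from
    ``lam_start`` down to ``lam_end``, with ``lam_end`` reached at the last
    sample (the endpoint / re-intubation time).  ``onset_frac`` delays the
    ramp: the rate holds at ``lam_start`` for that leading fraction of the
    record and then descends linearly, modelling slowing down that emerges
    only as the transition draws near.  ``lam_end`` must stay strictly
    positive: the stationary variance diverges at zero.
    """

    lam_start: float
    lam_end: float | None = None
    shape: str = "linear"
    onset_frac: float = 0.0

    def __post_init__(self) -> None:
        if not self.lam_start > 0:
            raise InvalidParameterError("lam_start must be > 0")
        if self.shape not in ("constant", "linear"):
            raise InvalidParameterError(f"unknown ramp shape {self.shape!r}")
        if not 0.0 <= self.onset_frac < 1.0:
            raise InvalidParameterError("onset_frac must lie in [0, 1)")
        if self.shape == "linear":
            if self.lam_end is None or not self.lam_end > 0:
                raise InvalidParameterError("lam_end must be > 0")
            if self.lam_end > self.lam_start:
                raise InvalidParameterError("lam_end must be <= lam_start")

    def rates(self, n: int) -> np.ndarray:
        """Decay rate at each of ``n`` samples of the record."""
        if self.shape == "constant" or n == 1:
            return np.full(n, self.lam_start)
        k0 = int(np.floor(self.onset_frac * (n - 1)))
        out = np.full(n, self.lam_start)
        out[k0:] = np.linspace(self.lam_start, self.lam_end, n - k0)
        return out


@dataclass(frozen=True)
class PatientRecord:
    """Metadata for one monitored extubation episode.

    Cohorts follow the study design: 1 = failed extubation, re-intubated,
    survived; 2 = successful extubation, survived (controls, assigned a
    pseudo-re-intubation endpoint); 3 = not re-intubated, died; 4 =
    re-intubated and died after re-intubation.
    """

    patient_id: str
    cohort: int
    ward: str
    age: float
    sex: str
    extubation_time: float  # seconds, arbitrary epoch
    endpoint_time: float    # re-intubation / pseudo-re-intubation / death
    death_flag: bool

    def __post_init__(self) -> None:
        if self.cohort not in (1, 2, 3, 4):
            raise InvalidParameterError(f"cohort must be 1-4, got {self.cohort}")
        if self.ward not in WARDS:
            raise InvalidParameterError(f"unknown ward {self.ward!r}")
        if self.sex not in SEXES:
            raise InvalidParameterError(f"unknown sex {self.sex!r}")
        if self.age < 0:
            raise InvalidParameterError("age must be >= 0")
        if not self.endpoint_time > self.extubation_time:
            raise InvalidParameterError("endpoint_time must be after extubation_time")
        if self.death_flag != (self.cohort in (3, 4)):
            raise InvalidParameterError(
                f"death_flag={self.death_flag} inconsistent with cohort {self.cohort}"
            )

    @property
    def duration(self) -> float:
        """Analyzed interval length in seconds."""
        return self.endpoint_time - self.extubation_time


@dataclass
class VitalSignSeries:
    """A uniformly sampled vital-sign series with explicit missingness (NaN).

    ``times`` are seconds since extubation on a constant 5 s grid.
    """

    variable: str
    times: np.ndarray
    values: np.ndarray

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.times.shape != self.values.shape or self.times.ndim != 1:
            raise InvalidParameterError("times and values must be 1-d and aligned")
        if len(self.times) < 2:
            raise InvalidParameterError("series needs at least 2 samples")
        steps = np.diff(self.times)
        if not np.allclose(steps, steps[0]):
            raise InvalidParameterError("sampling grid is not uniform")
        if not steps[0] > 0:
            raise InvalidParameterError("times must be strictly increasing")

    def __len__(self) -> int:
        return len(self.values)

    @property
    def dt(self) -> float:
        return float(self.times[1] - self.times[0])

    @property
    def missing_mask(self) -> np.ndarray:
        return np.isnan(self.values)


def closed_form_ou_moments(params: OUParams, tau: float) -> tuple[float, float]:
    """Stationary variance and lag-``tau`` autocorrelation of the OU model.

    Returns ``(sigma^2 / (2*lam), exp(-lam*tau))`` exactly.  As lam -> 0 the
    variance diverges and the autocorrelation tends to 1 — the signature of
    critical slowing down that the windowed indicators track.
    """
    if tau < 0:
        raise InvalidParameterError("tau must be >= 0")
    variance = params.sigma**2 / (2.0 * params.lam)
    acf = math.exp(-params.lam * tau)
    return variance, acf


def _ou_path(
    lam: np.ndarray | float,
    sigma: float,
    dt: float,
    n: int,
    rng: np.random.Generator,
    x0: float | None = None,
) -> np.ndarray:
    """Exact-discretization OU sample path with (possibly time-varying) lam.

    Uses x_k = phi_k x_{k-1} + w_k with phi_k = exp(-lam_k dt) and
    Var(w_k) = sigma^2 (1 - phi_k^2) / (2 lam_k), which is exact for
    piecewise-constant lam and removes Euler step-size bias at the coarse
    5 s grid.  Evaluated blockwise via a rescaled cumulative sum so that the
    running decay product never underflows.
    """
    lam_arr = np.broadcast_to(np.asarray(lam, dtype=float), (n,))
    if np.any(lam_arr <= 0):
        raise InvalidParameterError("lam must be > 0 everywhere")
    if x0 is None:
        x0 = rng.normal(0.0, sigma / math.sqrt(2.0 * lam_arr[0])) if sigma > 0 else 0.0

    x = np.empty(n)
    x[0] = x0
    if n == 1:
        return x
    lam_step = lam_arr[1:]
    phi = np.exp(-lam_step * dt)
    q = sigma**2 * (1.0 - phi**2) / (2.0 * lam_step)
    w = rng.normal(0.0, np.sqrt(q)) if sigma > 0 else np.zeros(n - 1)

    # Split into blocks whose cumulative log-decay stays modest (< ~200),
    # keeping 1/prod(phi) finite in double precision.
    log_decay = np.cumsum(lam_step * dt)
    block_ids = np.floor(log_decay / 200.0).astype(np.int64)
    xprev = x0
    pos = 1
    for _, count in zip(*np.unique(block_ids, return_counts=True)):
        sl = slice(pos - 1, pos - 1 + count)
        prod = np.cumprod(phi[sl])
        x[pos : pos + count] = prod * (xprev + np.cumsum(w[sl] / prod))
        xprev = x[pos + count - 1]
        pos += count
    return x


def simulate_ou(
    params: OUParams,
    n_steps: int,
    seed: int | np.random.Generator,
    x0: float | None = None,
    variable: str = "residual",
) -> VitalSignSeries:
    """Simulate a stationary OU residual series (baseline 0).

    The initial state is drawn from the stationary law N(0, sigma^2/(2*lam))
    unless ``x0`` is given; with ``sigma=0`` the path is the deterministic
    decay ``x0 * exp(-lam t)``.
    """
    if n_steps < 2:
        raise InvalidParameterError("n_steps must be >= 2")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    values = _ou_path(params.lam, params.sigma, params.dt, n_steps, rng, x0=x0)
    times = np.arange(n_steps) * params.dt
    return VitalSignSeries(variable=variable, times=times, values=values)


@dataclass(frozen=True)
class BaselineSpec:
    """Slowly varying baseline for one variable: mean plus optional sinusoidal
    drift (amplitude in signal units, period in seconds, random phase)."""

    mean: float
    drift_amplitude: float = 0.0
    drift_period_s: float = 7200.0


@dataclass(frozen=True)
class GapSpec:
    """Missing-data injection: per-sample start rates of short (<= 10 step)
    and long (> 10 step) gaps, with geometric run lengths."""

    short_rate: float = 0.002
    long_rate: float = 0.0003
    mean_short: float = 4.0
    mean_long: float = 30.0

    @classmethod
    def none(cls) -> "GapSpec":
        return cls(short_rate=0.0, long_rate=0.0)


#: Physiologically plausible paediatric defaults (config values, not claims).
DEFAULT_BASELINES: Mapping[str, BaselineSpec] = {
    "HR": BaselineSpec(mean=120.0, drift_amplitude=5.0),
    "RR": BaselineSpec(mean=30.0, drift_amplitude=2.0),
    "ABP": BaselineSpec(mean=60.0, drift_amplitude=3.0),
}

#: Residual noise amplitudes giving stationary SDs of a few signal units.
DEFAULT_SIGMAS: Mapping[str, float] = {"HR": 1.5, "RR": 0.9, "ABP": 1.1}


def _inject_gaps(values: np.ndarray, spec: GapSpec, rng: np.random.Generator) -> np.ndarray:
    n = len(values)
    miss = np.zeros(n, dtype=bool)
    for rate, lo, hi, mean in (
        (spec.short_rate, 1, 10, spec.mean_short),
        (spec.long_rate, 11, n, spec.mean_long),
    ):
        if rate <= 0:
            continue
        starts = np.flatnonzero(rng.random(n) < rate)
        lengths = np.clip(rng.geometric(1.0 / mean, size=starts.size), lo, hi)
        for s, length in zip(starts, lengths):
            miss[s : s + length] = True
    out = values.copy()
    out[miss] = np.nan
    return out


def simulate_record(
    record: PatientRecord,
    baselines: Mapping[str, BaselineSpec] | None = None,
    ramp: RampSchedule | Mapping[str, RampSchedule] | None = None,
    noise: Mapping[str, OUParams] | OUParams | None = None,
    gap_spec: GapSpec | None = None,
    seed: int | np.random.Generator = 0,
    variables: Sequence[str] = VARIABLES,
) -> dict[str, VitalSignSeries]:
    """Simulate the full set of vital-sign series for one record.

    The residual decay-rate schedule is taken from ``ramp``; failure records
    (cohort 1, optionally 4) should be given a ramp whose ``lam_end`` is
    reached exactly at ``endpoint_time``, controls a constant schedule.
    """
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    baselines = dict(DEFAULT_BASELINES) if baselines is None else baselines
    gap_spec = GapSpec() if gap_spec is None else gap_spec
    n = int(math.floor(record.duration / SAMPLE_INTERVAL_S)) + 1
    if n < 2:
        raise InvalidParameterError("record too short for the 5 s grid")
    times = np.arange(n) * SAMPLE_INTERVAL_S

    out: dict[str, VitalSignSeries] = {}
    for var in variables:
        base = baselines.get(var, BaselineSpec(mean=0.0))
        if isinstance(noise, OUParams):
            params = noise
        elif noise is not None and var in noise:
            params = noise[var]
        else:
            params = OUParams(lam=0.1, sigma=DEFAULT_SIGMAS.get(var, 1.0))
        var_ramp = ramp[var] if isinstance(ramp, Mapping) else ramp
        if var_ramp is None:
            var_ramp = RampSchedule(lam_start=params.lam, shape="constant")
        lam = var_ramp.rates(n)
        residual = _ou_path(lam, params.sigma, SAMPLE_INTERVAL_S, n, rng)
        phase = rng.uniform(0.0, 2.0 * math.pi)
        baseline = base.mean + base.drift_amplitude * np.sin(
            2.0 * math.pi * times / base.drift_period_s + phase
        )
        values = _inject_gaps(baseline + residual, gap_spec, rng)
        out[var] = VitalSignSeries(variable=var, times=times, values=values)
    return out


def sample_pseudo_duration(
    failure_durations: Sequence[float], rng: np.random.Generator
) -> float:
    """Draw a pseudo-re-intubation interval for a control record.

    Sampling with replacement from the empirical failure-duration
    distribution makes the analyzed-interval durations of controls match the
    failure cohort's distribution, so that trend tests see comparable record
    lengths in both groups.
    """
    durations = np.asarray(failure_durations, dtype=float)
    if durations.size == 0:
        raise InvalidParameterError("failure_durations must be non-empty")
    return float(rng.choice(durations))


@dataclass(frozen=True)
class CohortConfig:
    """Study conditions for one synthetic cohort dataset.

    Default cohort sizes match the evaluable heart-rate counts of the study
    design this generator mirrors (101 failures vs 1475 controls).  Failure
    records ramp the residual decay rate from ``lam_start`` to ``lam_end``
    across the analyzed interval; controls are stationary at ``lam_start``.
    """

    n_cohort1: int = 101
    n_cohort2: int = 1475
    n_cohort3: int = 0
    n_cohort4: int = 0
    ward_probs: tuple[float, float, float] = (0.25, 0.62, 0.13)  # PICU, CICU, NICU
    sex_probs: tuple[float, float, float] = (0.55, 0.44, 0.01)  # M, F, Unknown
    age_log_mean: float = 0.0   # log-years; median age 1 y
    age_log_sd: float = 1.2
    age_max: float = 18.0
    duration_log_median_s: float = math.log(6 * 3600.0)
    duration_log_sd: float = 0.7
    min_duration_s: float = 7200.0
    max_duration_s: float = 48 * 3600.0
    lam_start: float = 0.1      # 1/s; stationary control decay rate
    #: Per-record terminal decay rate of failure ramps, drawn log-uniformly:
    #: patients differ in how close to the transition they get before
    #: re-intubation, so early-warning strength varies across records.
    lam_end_range: tuple[float, float] = (0.005, 0.1)
    #: Fraction of the record elapsed before the ramp begins, drawn
    #: uniformly per failure record: slowing down emerges late and at a
    #: patient-specific time, so some records carry little detectable signal.
    onset_frac_range: tuple[float, float] = (0.2, 0.9)
    ramp_cohort4: bool = True
    sigmas: Mapping[str, float] = field(default_factory=lambda: dict(DEFAULT_SIGMAS))
    baselines: Mapping[str, BaselineSpec] = field(
        default_factory=lambda: dict(DEFAULT_BASELINES)
    )
    gap_spec: GapSpec = field(default_factory=GapSpec)
    #: Probability that a variable was recorded at all for a given patient,
    #: mirroring the unequal per-variable availability of real monitor data.
    variable_availability: Mapping[str, float] = field(
        default_factory=lambda: {"HR": 1.0, "RR": 0.84, "ABP": 0.70}
    )
    include_ineligible: int = 0  # records shorter than 120 min, for filter tests


def _truncated_lognormal(
    rng: np.random.Generator, log_median: float, log_sd: float, lo: float, hi: float, size: int
) -> np.ndarray:
    out = np.empty(size)
    remaining = np.arange(size)
    while remaining.size:
        draws = rng.lognormal(log_median, log_sd, size=remaining.size)
        ok = (draws >= lo) & (draws <= hi)
        out[remaining[ok]] = draws[ok]
        remaining = remaining[~ok]
    return out


def generate_cohort(
    config: CohortConfig, seed: int
) -> tuple[list[PatientRecord], dict[str, dict[str, VitalSignSeries]]]:
    """Generate the labelled records and series of one synthetic cohort.

    All randomness flows from ``seed``; repeated calls with the same config
    and seed reproduce the dataset bit for bit.
    """
    rng = np.random.default_rng(seed)
    sizes = {
        1: config.n_cohort1,
        2: config.n_cohort2,
        3: config.n_cohort3,
        4: config.n_cohort4,
    }
    grid = SAMPLE_INTERVAL_S

    # Failure-interval durations; controls resample from the cohort-1 pool.
    n1 = sizes[1]
    failure_durations = _truncated_lognormal(
        rng, config.duration_log_median_s, config.duration_log_sd,
        config.min_duration_s, config.max_duration_s, max(n1, 1),
    )
    failure_durations = np.round(failure_durations / grid) * grid

    records: list[PatientRecord] = []
    store: dict[str, dict[str, VitalSignSeries]] = {}
    idx = 0
    for cohort in (1, 2, 3, 4):
        for i in range(sizes[cohort]):
            idx += 1
            pid = f"SYN{idx:05d}"
            ward = WARDS[rng.choice(3, p=np.asarray(config.ward_probs))]
            sex = SEXES[rng.choice(3, p=np.asarray(config.sex_probs))]
            age = min(
                float(rng.lognormal(config.age_log_mean, config.age_log_sd)),
                config.age_max,
            )
            if cohort == 1:
                duration = float(failure_durations[i])
            elif cohort == 2 and n1 > 0:
                duration = sample_pseudo_duration(failure_durations, rng)
            else:
                duration = float(
                    np.round(
                        _truncated_lognormal(
                            rng, config.duration_log_median_s, config.duration_log_sd,
                            config.min_duration_s, config.max_duration_s, 1,
                        )[0]
                        / grid
                    )
                    * grid
                )
            ext_time = float(rng.integers(0, 3 * 365 * 86400 // 5)) * grid
            record = PatientRecord(
                patient_id=pid,
                cohort=cohort,
                ward=ward,
                age=round(age, 3),
                sex=sex,
                extubation_time=ext_time,
                endpoint_time=ext_time + duration,
                death_flag=cohort in (3, 4),
            )
            ramped = cohort == 1 or (cohort == 4 and config.ramp_cohort4)
            if ramped:
                lo, hi = config.lam_end_range
                lam_end = min(float(np.exp(rng.uniform(np.log(lo), np.log(hi)))),
                              config.lam_start)
                onset = float(rng.uniform(*config.onset_frac_range))
                ramp = RampSchedule(config.lam_start, lam_end, shape="linear",
                                    onset_frac=onset)
            else:
                ramp = RampSchedule(config.lam_start, shape="constant")
            available = [
                v
                for v in VARIABLES
                if rng.random() < config.variable_availability.get(v, 1.0)
            ] or ["HR"]
            noise = {
                v: OUParams(lam=config.lam_start, sigma=config.sigmas.get(v, 1.0))
                for v in available
            }
            store[pid] = simulate_record(
                record,
                baselines=config.baselines,
                ramp=ramp,
                noise=noise,
                gap_spec=config.gap_spec,
                seed=rng,
                variables=available,
            )
            records.append(record)

    # Deliberately ineligible records (< 120 min) to exercise the filter.
    for j in range(config.include_ineligible):
        idx += 1
        pid = f"SYN{idx:05d}"
        duration = float(rng.integers(2, int(config.min_duration_s // grid))) * grid
        ext_time = float(rng.integers(0, 3 * 365 * 86400 // 5)) * grid
        record = PatientRecord(
            patient_id=pid, cohort=2, ward="PICU", age=1.0, sex="M",
            extubation_time=ext_time, endpoint_time=ext_time + duration,
            death_flag=False,
        )
        store[pid] = simulate_record(
            record, baselines=config.baselines,
            ramp=RampSchedule(config.lam_start, shape="constant"),
            gap_spec=config.gap_spec, seed=rng, variables=["HR"],
        )
        records.append(record)

    return records, store


def generate_cohort_dataset(config: CohortConfig, seed: int, out_dir):
    """Generate a cohort and write it in the pipeline's input formats.

    Returns ``(records, store, manifest_path)``.  See :mod:`icuews.io` for
    the on-disk layout (metadata CSV, per-series CSV files, JSON manifest).
    """
    from . import io as _io

    records, store = generate_cohort(config, seed)
    manifest_path = _io.write_dataset(out_dir, records, store, config=config, seed=seed)
    return records, store, manifest_path
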