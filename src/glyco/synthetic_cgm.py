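"""Seedable synthetic CGM cohorts with realistic class imbalance.

The generator emulates the statistical structure of a T2D outpatient CGM
cohort: ~40 patients, basal glucose around 130.6 mg/dL, sensor range
40-400 mg/dL, recording lengths lognormal around a 90 h median, and
hypoglycemia (BG < 80 mg/dL) as a strongly under-represented class (roughly
5% of samples at defaults).

Each trace is a sum of interpretable components:

* a basal level with per-patient multiplicative jitter,
* a sinusoidal circadian oscillation,
* meal excursions (fast rise, slow exponential decay) large enough to cross
  the 180 mg/dL hyperglycemia threshold,
* occasional smooth hypoglycemic dips below 80 mg/dL,
* stationary AR(1) sensor noise,

clipped to the sensor range, with missing samples injected at a fixed rate.
This is a documented stand-in, not a physiological glucose-insulin model.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, replace

import numpy as np

from .cgm_data import (GlucoseSeries, SAMPLE_MINUTES, SENSOR_MAX, SENSOR_MIN)

__all__ = ["SyntheticCohortConfig", "simulate_patient", "simulate_cohort",
           "apply_cgm_artifact"]

_MINUTES_PER_DAY = 1440.0


@dataclass(frozen=True)
class SyntheticCohortConfig:
    """Cohort-level generative parameters (all glucose terms in mg/dL)."""

    n_patients: int = 40
    #: fixed per-patient recording length; None draws from the lognormal below
    duration_hours: float | None = None
    duration_median_hours: float = 90.0
    #: lognormal sigma fitted to the 82-170 h interquartile spread
    duration_log_sigma: float = 0.54
    basal_mean: float = 130.6
    circadian_amplitude: float = 15.0
    meal_events_per_day: float = 3.0
    meal_rise: float = 60.0
    meal_rise_minutes: float = 15.0
    meal_decay_minutes: float = 60.0
    hypo_event_rate: float = 3.0
    hypo_trough_range: tuple[float, float] = (50.0, 70.0)
    hypo_width_minutes: float = 25.0
    noise_sd: float = 5.0
    noise_rho: float = 0.7
    missing_rate: float = 0.02
    #: multiplicative per-patient jitter (lognormal sigma) on basal and meals
    basal_jitter_sigma: float = 0.05
    meal_jitter_sigma: float = 0.15
    seed: int = 0

    def to_dict(self) -> dict:
        d = asdict(self)
        d["hypo_trough_range"] = list(d["hypo_trough_range"])
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SyntheticCohortConfig":
        d = dict(d)
        if "hypo_trough_range" in d:
            d["hypo_trough_range"] = tuple(d["hypo_trough_range"])
        return cls(**d)


def _meal_pulse(dt_minutes: np.ndarray, rise: float, decay: float) -> np.ndarray:
    """Unit-peak double-exponential pulse: sharp uptake, slow clearance."""
    t_peak = np.log(decay / rise) / (1.0 / rise - 1.0 / decay)
    norm = np.exp(-t_peak / decay) - np.exp(-t_peak / rise)
    dt = np.maximum(dt_minutes, 0.0)
    out = np.exp(-dt / decay) - np.exp(-dt / rise)
    return out / norm


def simulate_patient(config: SyntheticCohortConfig, patient_seed: int,
                     patient_id: str | None = None) -> GlucoseSeries:
    """Simulate one patient's 5-min CGM trace; bit-reproducible per seed."""
    rng = np.random.default_rng(patient_seed)
    if config.duration_hours is not None:
        duration_h = float(config.duration_hours)
    else:
        duration_h = float(config.duration_median_hours *
                           np.exp(config.duration_log_sigma * rng.standard_normal()))
    if duration_h <= 0:
        raise ValueError("patient recording duration must be positive")
    n = max(int(round(duration_h * 60 / SAMPLE_MINUTES)), 1)
    t = np.arange(n) * float(SAMPLE_MINUTES)
    days = n * SAMPLE_MINUTES / _MINUTES_PER_DAY

    phase = rng.uniform(0, 2 * np.pi)
    trace = config.basal_mean + config.circadian_amplitude * np.sin(
        2 * np.pi * t / _MINUTES_PER_DAY + phase)

    n_meals = rng.poisson(config.meal_events_per_day * days)
    for _ in range(n_meals):
        onset = rng.uniform(0, t[-1] if n > 1 else 1.0)
        amp = config.meal_rise * np.exp(0.2 * rng.standard_normal())
        trace += amp * _meal_pulse(t - onset, config.meal_rise_minutes,
                                   config.meal_decay_minutes)

    n_dips = rng.poisson(config.hypo_event_rate * days)
    for _ in range(n_dips):
        center = rng.uniform(0, t[-1] if n > 1 else 1.0)
        trough = rng.uniform(*config.hypo_trough_range)
        depth = max(config.basal_mean - trough, 0.0)
        trace -= depth * np.exp(-0.5 * ((t - center) / config.hypo_width_minutes) ** 2)

    if config.noise_sd > 0:
        z = rng.standard_normal(n)
        noise = np.empty(n)
        noise[0] = z[0] * config.noise_sd
        c = np.sqrt(1.0 - config.noise_rho ** 2) * config.noise_sd
        for i in range(1, n):
            noise[i] = config.noise_rho * noise[i - 1] + c * z[i]
        trace += noise

    trace = np.clip(trace, SENSOR_MIN, SENSOR_MAX)
    gap = rng.uniform(size=n) < config.missing_rate
    trace[gap] = np.nan
    return GlucoseSeries(patient_id=patient_id or f"synth-{patient_seed}",
                         values=trace, gap_mask=gap)


def simulate_cohort(config: SyntheticCohortConfig) -> list[GlucoseSeries]:
    """Simulate ``config.n_patients`` independent patients.

    Per-patient seeds and multiplicative jitter on basal level and meal
    amplitude all derive from the master seed, so the cohort is
    bit-reproducible and patients are heterogeneous enough for a
    population/individual transfer-learning distinction.
    """
    master = np.random.default_rng(config.seed)
    series = []
    for i in range(config.n_patients):
        pseed = int(master.integers(0, 2 ** 31 - 1))
        basal = config.basal_mean * np.exp(
            config.basal_jitter_sigma * master.standard_normal())
        rise = config.meal_rise * np.exp(
            config.meal_jitter_sigma * master.standard_normal())
        patient_cfg = replace(config, basal_mean=float(basal), meal_rise=float(rise))
        series.append(simulate_patient(patient_cfg, pseed, patient_id=f"P{i:03d}"))
    return series


def apply_cgm_artifact(series: GlucoseSeries, bias_mgdl: float,
                       threshold_mgdl: float = 80.0) -> GlucoseSeries:
    """Emulate the real-time CGM low-range measurement artifact.

    Readings whose true value is below ``threshold_mgdl`` are reported
    ``bias_mgdl`` higher (capped at the threshold) — the underestimation of
    hypoglycemia depth that motivates using 80 mg/dL rather than 70 mg/dL as
    the operational hypoglycemia threshold.
    """
    if bias_mgdl < 0:
        raise ValueError("bias must be non-negative")
    v = series.values_mgdl.copy()
    low = ~series.gap_mask & (v < threshold_mgdl)
    v[low] = np.minimum(v[low] + bias_mgdl, threshold_mgdl)
    return replace(series, values=v * series.scale, gap_mask=series.gap_mask.copy())
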