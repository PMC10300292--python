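"""Synthetic heart-rate and seizure-diary generator with known ground truth.

Emulates the structure of real wearable recordings: a baseline heart rate
modulated by a sum of sinusoidal cycles (daily / weekly / fortnightly /
monthly), AR(1) noise, and contiguous non-wear gaps; and a self-reported
seizure diary whose events are phase-locked, with von Mises concentration
``kappa``, to a chosen subset of the planted cycles. Every downstream stage
of the pipeline can therefore be tested against a known answer.
"""
from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence, Optional

import numpy as np
from scipy import signal as sps
from scipy import stats

from .containers import HR_STEP, DAY, EventDiary, HeartRateSeries, wrap_phase

__all__ = ["ScenarioConfig", "generate_hr", "generate_events", "ground_truth",
           "write_ground_truth"]

#: 5-minute samples per day
_SAMPLES_PER_DAY = 288

#: mean non-wear gap length, in 5-minute samples (6 hours)
_MEAN_GAP_SAMPLES = 72


@dataclass
class ScenarioConfig:
    """Parameters of one synthetic recording scenario.

    Defaults emulate a typical long-term wearable recording: ~6 months of
    data, a 75 BPM baseline with daily/weekly/2-weekly/monthly cycles, an
    18% device non-wear fraction and ~0.22 reported seizures per day locked
    to the 2-weekly cycle with moderate concentration.
    """

    duration_days: float = 180.0
    hr_baseline: float = 75.0
    cycle_periods: Sequence[float] = (1.0, 7.0, 14.0, 28.0)
    cycle_amplitudes: Sequence[float] = (5.0, 3.0, 3.0, 3.0)
    cycle_phases: Optional[Sequence[float]] = None
    noise_sd: float = 5.0
    ar1_coeff: float = 0.8
    missing_fraction: float = 0.18
    event_rate: float = 0.22
    locking_periods: Sequence[float] = (14.0,)
    kappa: float = 2.0
    seed: int = 0
    start_time: np.datetime64 = field(
        default_factory=lambda: np.datetime64("2020-01-01T00:00:00", "ns"))

    def __post_init__(self):
        self.cycle_periods = tuple(float(p) for p in self.cycle_periods)
        self.cycle_amplitudes = tuple(float(a) for a in self.cycle_amplitudes)
        if self.cycle_phases is None:
            self.cycle_phases = tuple(0.0 for _ in self.cycle_periods)
        else:
            self.cycle_phases = tuple(float(p) for p in self.cycle_phases)
        self.locking_periods = tuple(float(p) for p in self.locking_periods)
        self.start_time = np.datetime64(self.start_time, "ns")
        if not self.duration_days > 0:
            raise ValueError("duration_days must be positive")
        if any(p <= 0 for p in self.cycle_periods):
            raise ValueError("cycle_periods must be strictly positive")
        if len(set(self.cycle_periods)) != len(self.cycle_periods):
            raise ValueError("cycle_periods must be distinct")
        if len(self.cycle_amplitudes) != len(self.cycle_periods):
            raise ValueError("cycle_amplitudes must match cycle_periods in length")
        if len(self.cycle_phases) != len(self.cycle_periods):
            raise ValueError("cycle_phases must match cycle_periods in length")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        if not 0.0 <= self.ar1_coeff < 1.0:
            raise ValueError("ar1_coeff must lie in [0, 1)")
        if not 0.0 <= self.missing_fraction < 1.0:
            raise ValueError("missing_fraction must lie in [0, 1)")
        if self.event_rate < 0:
            raise ValueError("event_rate must be non-negative")
        if any(p <= 0 for p in self.locking_periods):
            raise ValueError("locking_periods must be strictly positive")
        if self.kappa < 0:
            raise ValueError("kappa must be non-negative")

    @property
    def n_samples(self) -> int:
        return int(round(self.duration_days * _SAMPLES_PER_DAY))


def _ar1_noise(rng: np.random.Generator, n: int, sd: float, a: float) -> np.ndarray:
    """AR(1) noise whose marginal (stationary) SD equals ``sd``."""
    if sd == 0.0 or n == 0:
        return np.zeros(n)
    innovations = rng.normal(0.0, sd * np.sqrt(1.0 - a * a), n)
    x0 = rng.normal(0.0, sd)
    # x[i] = a*x[i-1] + e[i], seeded from the stationary distribution
    out, _ = sps.lfilter([1.0], [1.0, -a], innovations, zi=[a * x0])
    return out


def _contiguous_mask(rng: np.random.Generator, n: int, fraction: float) -> np.ndarray:
    """Mask ``round(fraction*n)`` samples in contiguous geometric-length blocks."""
    mask = np.zeros(n, dtype=bool)
    target = int(round(fraction * n))
    masked = 0
    while masked < target:
        start = int(rng.integers(0, n))
        length = int(rng.geometric(1.0 / _MEAN_GAP_SAMPLES))
        stop = min(start + length, n)
        block = mask[start:stop]
        fresh = np.flatnonzero(~block)
        if masked + fresh.size > target:
            fresh = fresh[: target - masked]
        mask[start + fresh] = True
        masked += fresh.size
    return mask


def generate_hr(config: ScenarioConfig) -> HeartRateSeries:
    """Simulate a 5-minute heart-rate series for the scenario.

    value(t) = baseline + sum_k A_k cos(2 pi t / P_k + phi_k) + AR(1) noise,
    with ``missing_fraction`` of samples masked in contiguous non-wear blocks.
    Bit-identical output for a fixed seed.
    """
    rng = np.random.default_rng([config.seed, 0])
    n = config.n_samples
    t_days = np.arange(n) / _SAMPLES_PER_DAY
    values = np.full(n, config.hr_baseline, dtype=float)
    for period, amp, phi in zip(config.cycle_periods, config.cycle_amplitudes,
                                config.cycle_phases):
        values += amp * np.cos(2.0 * np.pi * t_days / period + phi)
    values += _ar1_noise(rng, n, config.noise_sd, config.ar1_coeff)
    mask = _contiguous_mask(rng, n, config.missing_fraction)
    return HeartRateSeries(start_time=config.start_time, values=values,
                           missing_mask=mask, step=HR_STEP)


def _locking_phase_offsets(config: ScenarioConfig) -> dict:
    """Planted sinusoid phase offset for each locking period (0 if the period
    is a pure sinusoid reference rather than one of the HR cycles)."""
    offsets = {}
    for period in config.locking_periods:
        if period in config.cycle_periods:
            offsets[period] = config.cycle_phases[config.cycle_periods.index(period)]
        else:
            offsets[period] = 0.0
    return offsets


def generate_events(config: ScenarioConfig, hr: HeartRateSeries) -> EventDiary:
    """Draw phase-locked events by thinning a homogeneous rate.

    The per-sample intensity is ``event_rate`` modulated by the product of
    von Mises densities (concentration ``kappa``, mean at each locking
    cycle's peak), renormalised so the expected count stays at
    ``event_rate * duration``. Events land on the 5-minute grid.
    """
    rng = np.random.default_rng([config.seed, 1])
    n = hr.n
    if n == 0 or config.event_rate == 0.0:
        return EventDiary(np.empty(0, dtype="datetime64[ns]"))
    t_days = np.arange(n) / _SAMPLES_PER_DAY
    multiplier = np.ones(n)
    offsets = _locking_phase_offsets(config)
    for period in config.locking_periods:
        theta = wrap_phase(2.0 * np.pi * t_days / period + offsets[period])
        multiplier *= 2.0 * np.pi * stats.vonmises.pdf(theta, config.kappa)
    mean = multiplier.mean()
    if mean > 0:
        multiplier /= mean
    p = np.clip(config.event_rate / _SAMPLES_PER_DAY * multiplier, 0.0, 1.0)
    hits = rng.random(n) < p
    return EventDiary(hr.times[hits])


def ground_truth(config: ScenarioConfig) -> dict:
    """Planted structure of the scenario, for use as a test oracle.

    ``event_mean_phases`` gives, per locking period, the preferred event
    phase in the fixed-sinusoid convention referenced to the record start.
    """
    offsets = _locking_phase_offsets(config)
    return {
        "cycle_periods": list(config.cycle_periods),
        "cycle_amplitudes": list(config.cycle_amplitudes),
        "cycle_phases": list(config.cycle_phases),
        "locking_periods": list(config.locking_periods),
        "event_mean_phases": {str(p): wrap_phase(-offsets[p])
                              for p in config.locking_periods},
        "kappa": config.kappa,
        "event_rate": config.event_rate,
        "seed": config.seed,
        "duration_days": config.duration_days,
        "start_time": str(config.start_time),
    }


def write_ground_truth(config: ScenarioConfig, path) -> None:
    Path(path).write_text(json.dumps(ground_truth(config), indent=2) + "\n")
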