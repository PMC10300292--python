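"""Multiday cycle detection and instantaneous phase computation.

Heart-rate cycles are found as significant local maxima of the global
Morlet wavelet power spectrum against a red-noise background, then
extracted with a zero-phase second-order Butterworth bandpass (30% of the
central frequency by default) and converted to instantaneous phase with the
Hilbert transform. Seizure-diary cycles are found by scanning candidate
periods (1-70 days in 0.5-day steps, capped at half the record) and
retaining those whose events phase-lock with synchronization index
SI >= 0.3 under a fixed sinusoid phase.
"""
from __future__ import annotations

from typing import Optional

import numpy as np
from scipy import signal as sps

from .containers import (HOUR, CycleSpec, EventDiary, HeartRateSeries,
                         PhaseSeries, days_since, hour_grid, wrap_phase)
from .wavelet import global_wavelet_spectrum

__all__ = [
    "fill_missing",
    "band_edges",
    "detect_hr_cycles",
    "extract_cycle",
    "hilbert_phase",
    "candidate_periods",
    "sinusoid_phase",
    "compute_si",
    "detect_event_cycles",
]

#: default SI inclusion threshold for diary cycles
DEFAULT_SI_THRESHOLD = 0.3
#: default bandpass half-width as a fraction of the central frequency
DEFAULT_BANDWIDTH = 0.3


def fill_missing(hr: HeartRateSeries, training_mean: Optional[float] = None
                 ) -> HeartRateSeries:
    """Replace masked samples by a constant (the training-period mean HR).

    The mask is retained as metadata on the returned series. If
    ``training_mean`` is omitted, the mean of the observed samples is used;
    an all-missing series then raises.
    """
    if training_mean is None:
        training_mean = hr.observed_mean()
    if not np.isfinite(training_mean):
        raise ValueError("training_mean must be finite")
    values = hr.values.copy()
    values[hr.missing_mask] = training_mean
    return HeartRateSeries(start_time=hr.start_time, values=values,
                           missing_mask=hr.missing_mask.copy(), step=hr.step)


def band_edges(period: float, bandwidth_fraction: float = DEFAULT_BANDWIDTH
               ) -> tuple[float, float]:
    """Bandpass edges (days) for a cycle: ``period * (1 -/+ fraction)``."""
    if not period > 0:
        raise ValueError("period must be positive")
    if not 0.0 < bandwidth_fraction < 1.0:
        raise ValueError("bandwidth_fraction must lie in (0, 1)")
    return period * (1.0 - bandwidth_fraction), period * (1.0 + bandwidth_fraction)


def detect_hr_cycles(hr: HeartRateSeries, significance: float = 0.95, *,
                     bandwidth_fraction: float = DEFAULT_BANDWIDTH,
                     min_period: float = 2.0 / 24.0) -> list[CycleSpec]:
    """Significant heart-rate cycles from the global wavelet spectrum.

    The (gap-filled) series is averaged to hourly resolution and z-scored;
    cycles are local maxima of the time-averaged Morlet power exceeding the
    red-noise significance level at the given confidence, with periods
    capped at half the record length. Peak periods are refined by quadratic
    interpolation in log-scale. Returns cycles sorted by power, descending.
    """
    times, values = hr.hourly_means()
    n = values.size
    if n < 8:
        return []
    sd = values.std()
    if sd == 0.0:
        return []
    z = (values - values.mean()) / sd
    dt = 1.0 / 24.0  # days per hourly sample
    span_days = n * dt
    spectrum = global_wavelet_spectrum(z, dt, s0=max(min_period, 2.0 * dt) / 1.0330,
                                   max_period=span_days / 2.0,
                                   confidence=significance)
    if spectrum.periods.size < 3:
        return []
    g, sig, periods = spectrum.power, spectrum.significance, spectrum.periods
    peaks = []
    for i in range(1, g.size - 1):
        if not (g[i] > g[i - 1] and g[i] >= g[i + 1]):
            continue
        if g[i] <= sig[i]:
            continue
        # quadratic refinement of the peak location in log2(scale)
        denom = g[i - 1] - 2.0 * g[i] + g[i + 1]
        delta = 0.0 if denom == 0 else 0.5 * (g[i - 1] - g[i + 1]) / denom
        delta = float(np.clip(delta, -0.5, 0.5))
        period = periods[i] * 2.0 ** (delta * spectrum.dj)
        if period > span_days / 2.0:
            continue
        peaks.append((float(period), float(g[i])))
    # merge near-duplicates (within one scale step), keeping higher power
    peaks.sort(key=lambda p: -p[1])
    kept: list[tuple[float, float]] = []
    step_ratio = 2.0 ** spectrum.dj
    for period, power in peaks:
        if any(max(period, q) / min(period, q) < step_ratio for q, _ in kept):
            continue
        kept.append((period, power))
    cycles = []
    for period, power in kept:
        low, high = band_edges(period, bandwidth_fraction)
        cycles.append(CycleSpec(source="hr", period=period, band_low=low,
                                band_high=high, power=power))
    return cycles


def extract_cycle(hr: HeartRateSeries, cycle: CycleSpec) -> np.ndarray:
    """Bandpass-filter the series at the cycle's band (same 5-minute grid).

    Zero-phase (forward-backward) second-order Butterworth between
    ``band_low`` and ``band_high`` days, applied to the z-scored gap-filled
    series with reflection padding of one ``band_high`` length per side.
    """
    if cycle.band_low is None or cycle.band_high is None:
        raise ValueError("cycle has no band edges; use band_edges() first")
    fs = 86_400e9 / hr.step.astype("int64")  # samples per day
    nyquist = fs / 2.0
    f_low = 1.0 / cycle.band_high
    f_high = 1.0 / cycle.band_low
    if not 0.0 < f_low < f_high < nyquist:
        raise ValueError("cycle band outside representable frequencies")
    x = hr.values.astype(float)
    sd = x.std()
    z = (x - x.mean()) / sd if sd > 0 else x - x.mean()
    pad = min(int(round(cycle.band_high * fs)), z.size - 1)
    if pad > 0:
        z = np.pad(z, pad, mode="reflect")
    sos = sps.butter(2, [f_low, f_high], btype="bandpass", fs=fs, output="sos")
    y = sps.sosfiltfilt(sos, z)
    return y[pad:y.size - pad] if pad > 0 else y


def hilbert_phase(values: np.ndarray, start_time, step=None) -> PhaseSeries:
    """Instantaneous phase of a band-limited signal on the hourly grid.

    The analytic-signal angle is computed per input sample, unwrapped, and
    linearly interpolated to whole clock hours, then wrapped to (-pi, pi].
    """
    x = np.asarray(values, dtype=float)
    if x.size < 4:
        raise ValueError("signal too short for phase estimation")
    if not np.any(np.abs(x) > 1e-12 * max(1.0, np.abs(x).max(initial=0.0))) \
            or np.allclose(x, 0.0):
        raise ValueError("phase undefined for an all-zero signal")
    if step is None:
        step = np.timedelta64(5, "m")
    step = np.timedelta64(step).astype("timedelta64[ns]")
    start_time = np.datetime64(start_time, "ns")
    analytic = sps.hilbert(x)
    phase = np.unwrap(np.angle(analytic))
    times = start_time + np.arange(x.size) * step
    end = times[-1] + step
    grid = hour_grid(start_time, end)
    t = (times - times[0]).astype("int64").astype(float)
    tq = (grid - times[0]).astype("int64").astype(float)
    interp = np.interp(tq, t, phase)
    return PhaseSeries(times=grid, phase=wrap_phase(interp))


def candidate_periods(training_span_days: float) -> np.ndarray:
    """Candidate seizure-cycle periods: 1.0, 1.5, ... days, capped at
    min(70, half the training span)."""
    if not training_span_days > 0:
        raise ValueError("training span must be positive")
    cap = min(70.0, training_span_days / 2.0)
    if cap < 1.0:
        return np.empty(0)
    n = int(np.floor((cap - 1.0) / 0.5 + 1e-9)) + 1
    return 1.0 + 0.5 * np.arange(n)


def sinusoid_phase(times, period: float, reference_time) -> PhaseSeries:
    """Fixed-sinusoid phase: ``wrap(2 pi (t - reference) / period)``."""
    if not period > 0:
        raise ValueError("period must be positive")
    times = np.asarray(times, dtype="datetime64[ns]")
    t_days = days_since(times, reference_time)
    return PhaseSeries(times=times, phase=wrap_phase(2.0 * np.pi * t_days / period))


def compute_si(event_phases) -> float:
    """Synchronization index: modulus of the mean unit phasor.

    SI = |1/N sum_n exp(i theta_n)|, in [0, 1]; 1 means perfect phase
    locking, 0 a uniform phase distribution.
    """
    theta = np.asarray(event_phases, dtype=float)
    if theta.size == 0:
        raise ValueError("compute_si requires at least one phase")
    return float(np.abs(np.mean(np.exp(1j * theta))))


def detect_event_cycles(diary: EventDiary, training_span_days: float,
                        si_threshold: float = DEFAULT_SI_THRESHOLD, *,
                        reference_time=None,
                        merge_adjacent: bool = True) -> list[CycleSpec]:
    """Significant seizure cycles by SI scan over candidate periods.

    Each candidate period's SI is the phase-locking of event times under a
    fixed sinusoid referenced to ``reference_time`` (default: first event).
    Periods with SI >= ``si_threshold`` are retained; contiguous runs of
    passing candidates are merged to their max-SI member (harmonic peaks
    separated by failing candidates are kept as distinct cycles). Returns
    cycles sorted by SI, descending.
    """
    if len(diary) == 0:
        raise ValueError("detect_event_cycles requires at least one event")
    periods = candidate_periods(training_span_days)
    if periods.size == 0:
        return []
    if reference_time is None:
        reference_time = diary.times[0]
    t_days = days_since(diary.times, reference_time)
    # SI per candidate period, vectorised over the (events x periods) grid
    theta = 2.0 * np.pi * t_days[:, None] / periods[None, :]
    si = np.abs(np.mean(np.exp(1j * theta), axis=0))
    passing = si >= si_threshold
    selected: list[int] = []
    if merge_adjacent:
        i = 0
        while i < periods.size:
            if passing[i]:
                j = i
                while j + 1 < periods.size and passing[j + 1]:
                    j += 1
                run = np.arange(i, j + 1)
                selected.append(int(run[np.argmax(si[run])]))
                i = j + 1
            else:
                i += 1
    else:
        selected = list(np.flatnonzero(passing))
    cycles = [CycleSpec(source="diary", period=float(periods[k]),
                        si=float(min(si[k], 1.0)))
              for k in selected]
    cycles.sort(key=lambda c: -c.si)
    return cycles
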