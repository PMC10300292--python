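"""Forward projection of cycles for future risk estimation.

Heart-rate cycles are projected with an additive regression model
y(t) = g(t) + s(t) + e(t): a piecewise-linear trend g with penalised
changepoints plus Fourier seasonal terms

    s(t) = sum_{n=1..N} a_n cos(2 pi n t / P) + b_n sin(2 pi n t / P)

for each period P (daily, weekly, yearly defaults plus every detected HR
cycle), fitted by penalised least squares on the hourly-averaged gap-filled
series. The seasonal reconstruction of one cycle is then evaluated over the
future horizon, bandpassed at the cycle's band and converted to phase with
the same Hilbert procedure used on observed data. Seizure (diary) cycles
are projected exactly with the fixed sinusoid phase.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy import signal as sps

from .containers import (HOUR, CycleSpec, HeartRateSeries, PhaseSeries,
                         days_since, wrap_phase)
from .cycles import hilbert_phase, sinusoid_phase

__all__ = ["AdditiveModel", "fit_additive", "ProjectedCycle",
           "project_hr_cycle", "project_event_cycle"]

#: default seasonal periods always offered to the fit (days)
DEFAULT_PERIODS = (1.0, 7.0, 365.25)
#: Fourier order per seasonal period
YEARLY_ORDER = 10
DEFAULT_ORDER = 3
#: number of candidate trend changepoints (over the first 80% of the record)
N_CHANGEPOINTS = 25
#: L2 penalties (changepoint slopes; seasonal coefficients)
LAMBDA_DELTA = 10.0
LAMBDA_SEASONAL = 0.1


@dataclass
class SeasonalTerm:
    period: float
    order: int
    a: np.ndarray  # cosine coefficients, one per harmonic
    b: np.ndarray  # sine coefficients

    def evaluate(self, t_days: np.ndarray) -> np.ndarray:
        n = np.arange(1, self.order + 1)
        arg = 2.0 * np.pi * np.outer(t_days, n) / self.period
        return np.cos(arg) @ self.a + np.sin(arg) @ self.b

    def amplitude(self) -> float:
        """RMS-equivalent peak amplitude of the fundamental harmonic."""
        return float(np.hypot(self.a[0], self.b[0]))


@dataclass
class AdditiveModel:
    """Fitted additive trend + Fourier-seasonality model."""

    t0: np.datetime64                 # time origin of the fit
    fit_span_days: float              # extent of the training grid
    intercept: float
    slope: float
    changepoints: np.ndarray          # days since t0
    deltas: np.ndarray                # slope adjustments at changepoints
    seasonal: dict                    # period -> SeasonalTerm
    noise_sd: float

    def trend(self, t_days: np.ndarray) -> np.ndarray:
        t = np.asarray(t_days, dtype=float)
        out = self.intercept + self.slope * t
        for c, d in zip(self.changepoints, self.deltas):
            out = out + d * np.maximum(t - c, 0.0)
        return out

    def seasonal_component(self, period: float, t_days) -> np.ndarray:
        key = self._key(period)
        if key is None:
            raise ValueError(f"period {period} d is not a seasonal term of the model")
        return self.seasonal[key].evaluate(np.asarray(t_days, dtype=float))

    def predict(self, t_days) -> np.ndarray:
        t = np.asarray(t_days, dtype=float)
        out = self.trend(t)
        for term in self.seasonal.values():
            out = out + term.evaluate(t)
        return out

    def _key(self, period: float) -> Optional[float]:
        for p in self.seasonal:
            if abs(p - period) < 1e-9:
                return p
        return None

    def to_dict(self) -> dict:
        return {
            "t0": str(self.t0),
            "fit_span_days": self.fit_span_days,
            "intercept": self.intercept,
            "slope": self.slope,
            "changepoints": self.changepoints.tolist(),
            "deltas": self.deltas.tolist(),
            "seasonal": [{"period": term.period, "order": term.order,
                          "a": term.a.tolist(), "b": term.b.tolist()}
                         for term in self.seasonal.values()],
            "noise_sd": self.noise_sd,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "AdditiveModel":
        seasonal = {s["period"]: SeasonalTerm(s["period"], s["order"],
                                              np.asarray(s["a"]),
                                              np.asarray(s["b"]))
                    for s in d["seasonal"]}
        return cls(t0=np.datetime64(d["t0"], "ns"),
                   fit_span_days=d["fit_span_days"],
                   intercept=d["intercept"], slope=d["slope"],
                   changepoints=np.asarray(d["changepoints"]),
                   deltas=np.asarray(d["deltas"]),
                   seasonal=seasonal, noise_sd=d["noise_sd"])


def _fourier_order(period: float) -> int:
    return YEARLY_ORDER if period > 300 else DEFAULT_ORDER


def fit_additive(hr: HeartRateSeries, periods: Sequence[float] = (), *,
                 n_changepoints: int = N_CHANGEPOINTS) -> AdditiveModel:
    """Fit the additive model to the hourly-averaged (gap-filled) series.

    ``periods`` are the detected HR cycle periods; daily, weekly and yearly
    terms are always offered. Terms longer than the record are dropped with
    a warning. Seasonal coefficients and changepoint slope adjustments are
    L2-penalised; the base trend is not.
    """
    times, y = hr.hourly_means()
    if y.size < 24:
        raise ValueError("record too short to fit the additive model")
    t = days_since(times, times[0])
    span = float(t[-1])
    requested = sorted(set(float(p) for p in DEFAULT_PERIODS) |
                       set(float(p) for p in periods))
    kept = []
    for p in requested:
        if p > span:
            warnings.warn(f"seasonal period {p} d exceeds the record span; dropped")
        else:
            kept.append(p)
    changepoints = np.linspace(0.0, 0.8 * span, n_changepoints + 1)[1:]
    columns = [np.ones_like(t), t]
    penalties = [0.0, 0.0]
    for c in changepoints:
        columns.append(np.maximum(t - c, 0.0))
        penalties.append(LAMBDA_DELTA)
    seasonal_slices = {}
    for p in kept:
        order = _fourier_order(p)
        start = len(columns)
        n = np.arange(1, order + 1)
        arg = 2.0 * np.pi * np.outer(t, n) / p
        for k in range(order):
            columns.append(np.cos(arg[:, k]))
            penalties.append(LAMBDA_SEASONAL)
        for k in range(order):
            columns.append(np.sin(arg[:, k]))
            penalties.append(LAMBDA_SEASONAL)
        seasonal_slices[p] = (start, order)
    X = np.column_stack(columns)
    pen = np.asarray(penalties)
    gram = X.T @ X + np.diag(pen)
    beta = np.linalg.solve(gram, X.T @ y)
    resid = y - X @ beta
    seasonal = {}
    for p, (start, order) in seasonal_slices.items():
        a = beta[start:start + order]
        b = beta[start + order:start + 2 * order]
        seasonal[p] = SeasonalTerm(period=p, order=order, a=a.copy(), b=b.copy())
    return AdditiveModel(t0=times[0], fit_span_days=span,
                         intercept=float(beta[0]), slope=float(beta[1]),
                         changepoints=changepoints,
                         deltas=beta[2:2 + changepoints.size].copy(),
                         seasonal=seasonal, noise_sd=float(resid.std()))


@dataclass
class ProjectedCycle:
    """Projected cycle signal and phase over a future hourly grid."""

    cycle: CycleSpec
    times: np.ndarray
    values: np.ndarray
    phase: PhaseSeries
    degenerate: bool = False


def project_hr_cycle(model: AdditiveModel, cycle: CycleSpec,
                     horizon_days: float, issue_time=None) -> ProjectedCycle:
    """Project one HR cycle ``horizon_days`` past ``issue_time``.

    The cycle's seasonal component is evaluated over the training grid plus
    the future horizon, bandpassed at the cycle band (trend excluded), and
    converted to instantaneous phase with the Hilbert transform; the future
    hourly segment is returned. A near-zero seasonal reconstruction is
    flagged degenerate (its phase is meaningless).
    """
    if model._key(cycle.period) is None:
        raise ValueError(
            f"cycle period {cycle.period} d is not a seasonal term of the model")
    if issue_time is None:
        issue_time = model.t0 + np.timedelta64(
            int(round(model.fit_span_days * 86_400e9)), "ns")
    issue_time = np.datetime64(issue_time, "ns")
    n_future = int(round(horizon_days * 24))
    future = issue_time + np.arange(n_future) * HOUR
    if n_future == 0:
        empty = np.empty(0)
        return ProjectedCycle(cycle, future, empty,
                              PhaseSeries(future, empty), degenerate=False)
    # one uniform hourly grid from the fit origin through the horizon end,
    # analytically extended by two band_high lengths per side so that filter
    # and Hilbert edge transients fall outside the returned segment
    pad_hours = int(round(2.0 * (cycle.band_high or cycle.period) * 24))
    total = int((future[-1] + HOUR - model.t0) // HOUR)
    full = model.t0 + np.arange(-pad_hours, total + pad_hours) * HOUR
    t = days_since(full, model.t0)
    s = model.seasonal_component(cycle.period, t)
    if float(np.sqrt(np.mean(s * s))) < 1e-8:
        phase = PhaseSeries(future, np.zeros(n_future))
        return ProjectedCycle(cycle, future, np.zeros(n_future), phase,
                              degenerate=True)
    if cycle.band_low is not None and cycle.band_high is not None:
        fs = 24.0  # samples per day on the hourly grid
        f_low, f_high = 1.0 / cycle.band_high, 1.0 / cycle.band_low
        f_high = min(f_high, fs / 2.0 * 0.99)
        sos = sps.butter(2, [f_low, f_high], btype="bandpass", fs=fs,
                         output="sos")
        s = sps.sosfiltfilt(sos, s)
    ph = hilbert_phase(s, full[0], step=HOUR)
    sel = (ph.times >= future[0]) & (ph.times <= future[-1])
    phase = PhaseSeries(ph.times[sel], ph.phase[sel])
    sel_v = (full >= future[0]) & (full <= future[-1])
    return ProjectedCycle(cycle, future, s[sel_v], phase, degenerate=False)


def project_event_cycle(cycle: CycleSpec, reference_time, issue_time,
                        horizon_days: float) -> PhaseSeries:
    """Project a diary cycle: fixed sinusoid phase over the future hourly grid."""
    if cycle.source != "diary":
        raise ValueError("project_event_cycle expects a diary cycle")
    issue_time = np.datetime64(issue_time, "ns")
    n_future = int(round(horizon_days * 24))
    future = issue_time + np.arange(n_future) * HOUR
    return sinusoid_phase(future, cycle.period, reference_time)
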