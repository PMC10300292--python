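"""Core data containers shared across the forecasting pipeline.

Time is represented with ``numpy.datetime64[ns]`` throughout; all timestamps
are interpreted as UTC. Heart-rate samples live on a uniform 5-minute grid,
phases and forecasts on an hourly grid.
"""
from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np

HR_STEP = np.timedelta64(5, "m").astype("timedelta64[ns]")
HOUR = np.timedelta64(1, "h").astype("timedelta64[ns]")
DAY = np.timedelta64(1, "D").astype("timedelta64[ns]")

__all__ = [
    "HR_STEP",
    "HOUR",
    "DAY",
    "wrap_phase",
    "hour_grid",
    "floor_time",
    "midnight_after",
    "HeartRateSeries",
    "EventDiary",
    "CycleSpec",
    "PhaseSeries",
]


def wrap_phase(x):
    """Wrap angles (radians) into the half-open interval (-pi, pi]."""
    x = np.asarray(x, dtype=float)
    out = np.pi - np.mod(np.pi - x, 2.0 * np.pi)
    if out.ndim == 0:
        return float(out)
    return out


def _as_ns(t) -> np.datetime64:
    return np.datetime64(t, "ns")


def floor_time(t, unit: np.timedelta64) -> np.datetime64:
    """Floor a timestamp to a multiple of ``unit`` (anchored at the epoch)."""
    t = _as_ns(t)
    ns = int(t.astype("int64"))
    u = int(np.timedelta64(unit).astype("timedelta64[ns]").astype("int64"))
    return np.datetime64((ns // u) * u, "ns")


def midnight_after(t) -> np.datetime64:
    """The midnight (UTC) ending the calendar day containing ``t``."""
    return floor_time(t, DAY) + DAY


def hour_grid(start, end) -> np.ndarray:
    """Hourly timestamps in [start, end), beginning at the first whole hour >= start."""
    start = _as_ns(start)
    end = _as_ns(end)
    first = floor_time(start, HOUR)
    if first < start:
        first = first + HOUR
    if first >= end:
        return np.empty(0, dtype="datetime64[ns]")
    n = int((end - first) // HOUR)
    if first + n * HOUR < end:
        n += 1
    return first + np.arange(n) * HOUR


def days_since(times, reference) -> np.ndarray:
    """Elapsed time in (float) days from ``reference`` to each timestamp."""
    times = np.asarray(times, dtype="datetime64[ns]")
    ref = _as_ns(reference)
    return (times - ref).astype("int64") / 86_400e9


@dataclass
class HeartRateSeries:
    """Uniformly gridded heart-rate samples (BPM) with a missing-data mask.

    ``values[i]`` is the sample at ``start_time + i*step``; ``missing_mask[i]``
    is True where the sample is absent (the stored value is then ignored).
    """

    start_time: np.datetime64
    values: np.ndarray
    missing_mask: np.ndarray
    step: np.timedelta64 = field(default=HR_STEP)

    def __post_init__(self):
        self.start_time = _as_ns(self.start_time)
        self.values = np.asarray(self.values, dtype=float)
        self.missing_mask = np.asarray(self.missing_mask, dtype=bool)
        self.step = np.timedelta64(self.step).astype("timedelta64[ns]")
        if self.values.shape != self.missing_mask.shape:
            raise ValueError("values and missing_mask must have the same length")
        observed = self.values[~self.missing_mask]
        if observed.size and not np.all(np.isfinite(observed)):
            raise ValueError("non-finite heart-rate values outside the missing mask")

    @property
    def n(self) -> int:
        return self.values.size

    @property
    def times(self) -> np.ndarray:
        return self.start_time + np.arange(self.n) * self.step

    @property
    def end_time(self) -> np.datetime64:
        """Exclusive end of the record (start of the slot after the last sample)."""
        return self.start_time + self.n * self.step

    @property
    def span_days(self) -> float:
        return float((self.end_time - self.start_time).astype("int64") / 86_400e9)

    def observed_mean(self) -> float:
        observed = self.values[~self.missing_mask]
        if observed.size == 0:
            raise ValueError("series has no observed samples")
        return float(observed.mean())

    def slice_until(self, cutoff) -> "HeartRateSeries":
        """Samples strictly before ``cutoff``."""
        cutoff = _as_ns(cutoff)
        n = int(np.clip((cutoff - self.start_time) // self.step, 0, self.n))
        return replace(self, values=self.values[:n].copy(),
                       missing_mask=self.missing_mask[:n].copy())

    def hourly_means(self):
        """Hourly-mean series: (hour-start timestamps, means over each hour).

        Hours are aligned to whole clock hours; leading/trailing partial hours
        are dropped. Missing samples enter the mean as stored (call
        :func:`cycleforecast.cycles.fill_missing` first).
        """
        per = int(HOUR // self.step)
        first_hour = floor_time(self.start_time, HOUR)
        if first_hour < self.start_time:
            first_hour = first_hour + HOUR
        k0 = int((first_hour - self.start_time) // self.step)
        n_full = (self.n - k0) // per
        if n_full <= 0:
            return np.empty(0, dtype="datetime64[ns]"), np.empty(0)
        block = self.values[k0:k0 + n_full * per].reshape(n_full, per)
        times = first_hour + np.arange(n_full) * HOUR
        return times, block.mean(axis=1)


@dataclass
class EventDiary:
    """Ordered self-reported event (seizure) onset timestamps."""

    times: np.ndarray

    def __post_init__(self):
        t = np.asarray(self.times, dtype="datetime64[ns]")
        self.times = np.sort(t)

    def __len__(self) -> int:
        return self.times.size

    @property
    def n(self) -> int:
        return self.times.size

    def until(self, cutoff) -> "EventDiary":
        """Events strictly before ``cutoff`` (the training convention: an
        event exactly at a midnight cutoff belongs to the next day)."""
        return EventDiary(self.times[self.times < _as_ns(cutoff)])

    def between(self, start, end) -> "EventDiary":
        """Events with start <= t < end."""
        t = self.times
        return EventDiary(t[(t >= _as_ns(start)) & (t < _as_ns(end))])


@dataclass
class CycleSpec:
    """One detected cycle.

    HR cycles carry spectral ``power`` and bandpass ``band_low``/``band_high``
    edges (days); diary cycles carry the synchronization index ``si``.
    """

    source: str
    period: float
    band_low: Optional[float] = None
    band_high: Optional[float] = None
    si: Optional[float] = None
    power: Optional[float] = None

    def __post_init__(self):
        if self.source not in ("hr", "diary"):
            raise ValueError(f"unknown cycle source {self.source!r}")
        if not self.period > 0:
            raise ValueError("cycle period must be positive")
        if self.band_low is not None and self.band_high is not None:
            if not (0 < self.band_low < self.period < self.band_high):
                raise ValueError("band edges must bracket the period")
        if self.si is not None and not (0.0 <= self.si <= 1.0 + 1e-12):
            raise ValueError("SI must lie in [0, 1]")

    def to_dict(self) -> dict:
        return {
            "source": self.source,
            "period": self.period,
            "band_low": self.band_low,
            "band_high": self.band_high,
            "si": self.si,
            "power": self.power,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "CycleSpec":
        return cls(**d)


@dataclass
class PhaseSeries:
    """Instantaneous phase samples, wrapped to (-pi, pi]."""

    times: np.ndarray
    phase: np.ndarray

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype="datetime64[ns]")
        self.phase = wrap_phase(np.asarray(self.phase, dtype=float))
        if self.times.shape != self.phase.shape:
            raise ValueError("times and phase must have the same length")

    def phase_at(self, query_times) -> np.ndarray:
        """Phase at each query time, by exact lookup on the uniform grid.

        Query times are floored to the grid step first (an event at 13:42
        takes the phase of the 13:00 grid slot on an hourly grid).
        """
        if self.times.size < 2:
            raise ValueError("phase series too short for lookup")
        step = self.times[1] - self.times[0]
        q = np.asarray(query_times, dtype="datetime64[ns]")
        idx = (q - self.times[0]) // step
        idx = np.asarray(idx, dtype="int64")
        if np.any(idx < 0) or np.any(idx >= self.times.size):
            raise ValueError("query times outside the phase series span")
        return self.phase[idx]
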