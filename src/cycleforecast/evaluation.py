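"""Forecast scoring: time-in-warning ROC/AUC, Brier Skill Score, surrogate
significance and the time-of-day baseline.

The ROC here plots the fraction of time spent at or above a warning
threshold (the cost axis) against the fraction of event steps at or above
it (the benefit axis), as the threshold sweeps the forecast values; a step
is an hour (or a day at daily resolution) and event steps are those
containing at least one reported seizure. Significance is assessed by
recomputing the AUC for randomly relocated event steps.
"""
from __future__ import annotations

from dataclasses import dataclass
import numpy as np

from .containers import HOUR

__all__ = [
    "step_event_labels",
    "roc_auc",
    "operating_point",
    "brier_skill_score",
    "SurrogateResult",
    "surrogate_test",
    "time_of_day_baseline",
    "EvaluationReport",
]


def step_event_labels(step_times: np.ndarray, event_times) -> np.ndarray:
    """Boolean label per step: does the step contain >= 1 event?

    ``step_times`` is a uniform grid of step start times (hourly or daily);
    events are floored to the step and multiple events in one step count
    once.
    """
    step_times = np.asarray(step_times, dtype="datetime64[ns]")
    labels = np.zeros(step_times.size, dtype=bool)
    ev = np.asarray(event_times, dtype="datetime64[ns]")
    if ev.size == 0 or step_times.size == 0:
        return labels
    step = step_times[1] - step_times[0] if step_times.size > 1 else HOUR
    idx = (ev - step_times[0]) // step
    idx = np.asarray(idx, dtype="int64")
    ok = (idx >= 0) & (idx < step_times.size)
    labels[idx[ok]] = True
    return labels


class _TimeInWarningCurve:
    """Precomputed time-in-warning axis, reusable across many label sets."""

    def __init__(self, likelihood: np.ndarray):
        self.values = np.asarray(likelihood, dtype=float)
        self.n = self.values.size
        self.sorted = np.sort(self.values)
        self.thresholds = np.unique(self.sorted)
        # fraction of steps at/above each threshold (thresholds ascending)
        self.x = (self.n - np.searchsorted(self.sorted, self.thresholds,
                                           side="left")) / self.n

    def auc(self, event_values: np.ndarray) -> float:
        ne = event_values.size
        if ne == 0:
            raise ValueError("AUC requires at least one event step")
        if ne == self.n:
            raise ValueError("AUC requires at least one non-event step")
        es = np.sort(event_values)
        y = (ne - np.searchsorted(es, self.thresholds, side="left")) / ne
        # ascending x: reverse the threshold sweep; close with (0,0) and (1,1)
        xs = np.concatenate(([0.0], self.x[::-1], [1.0]))
        ys = np.concatenate(([0.0], y[::-1], [1.0]))
        return float(np.trapezoid(ys, xs))


def roc_auc(likelihood_series, event_labels) -> float:
    """Area under the time-in-warning ROC.

    x(threshold) = fraction of all steps with forecast >= threshold;
    y(threshold) = fraction of event steps with forecast >= threshold;
    integrated by trapezoid including the (0,0) and (1,1) endpoints.
    """
    L = np.asarray(likelihood_series, dtype=float)
    ev = np.asarray(event_labels, dtype=bool)
    if L.shape != ev.shape:
        raise ValueError("likelihood series and labels must align")
    if not ev.any():
        raise ValueError("AUC requires at least one event step")
    return _TimeInWarningCurve(L).auc(L[ev])


def operating_point(risk_labels, event_labels) -> tuple[float, float]:
    """(sensitivity, time-in-high) at the fitted thresholds.

    Sensitivity is the fraction of event steps labelled high risk;
    time-in-high the fraction of all steps labelled high.
    """
    risk = np.asarray(risk_labels)
    ev = np.asarray(event_labels, dtype=bool)
    high = risk == "high"
    time_in_high = float(high.mean()) if risk.size else 0.0
    sensitivity = float(high[ev].mean()) if ev.any() else float("nan")
    return sensitivity, time_in_high


def brier_skill_score(likelihood_series, event_labels,
                      reference_series=None) -> float:
    """BSS = 1 - BS/BS_ref; 1 for a perfect forecast, 0 for no improvement
    over the reference (a constant forecast at the mean event rate)."""
    L = np.asarray(likelihood_series, dtype=float)
    o = np.asarray(event_labels, dtype=float)
    if L.shape != o.shape:
        raise ValueError("likelihood series and labels must align")
    if reference_series is None:
        reference_series = np.full_like(o, o.mean())
    r = np.asarray(reference_series, dtype=float)
    bs = float(np.mean((L - o) ** 2))
    bs_ref = float(np.mean((r - o) ** 2))
    if bs_ref == 0.0:
        raise ValueError("reference Brier score is zero; BSS undefined")
    return 1.0 - bs / bs_ref


@dataclass
class SurrogateResult:
    observed_auc: float
    surrogate_aucs: np.ndarray
    p_value: float
    significant: bool


def surrogate_test(likelihood_series, event_labels, n_shuffles: int = 200,
                   seed=None, rng=None) -> SurrogateResult:
    """Shuffle-based significance of the forecast AUC.

    ``n_shuffles`` surrogate event sets (same number of event steps, drawn
    uniformly without replacement over all steps) are scored; the forecast
    is significant if its AUC exceeds 95% of surrogate AUCs. The p-value
    uses the add-one permutation convention (1 + #{surrogate >= observed})
    / (n_shuffles + 1).
    """
    L = np.asarray(likelihood_series, dtype=float)
    ev = np.asarray(event_labels, dtype=bool)
    ne = int(ev.sum())
    if ne == 0:
        raise ValueError("surrogate test requires at least one event step")
    if ne >= L.size:
        raise ValueError("more event steps than evaluable steps")
    if rng is None:
        rng = np.random.default_rng(seed)
    curve = _TimeInWarningCurve(L)
    observed = curve.auc(L[ev])
    surrogates = np.empty(n_shuffles)
    for k in range(n_shuffles):
        idx = rng.choice(L.size, size=ne, replace=False)
        surrogates[k] = curve.auc(L[idx])
    n_ge = int(np.sum(surrogates >= observed))
    n_lt = n_shuffles - n_ge
    significant = n_lt > 0.95 * n_shuffles
    p = (1.0 + n_ge) / (n_shuffles + 1.0)
    return SurrogateResult(observed_auc=observed, surrogate_aucs=surrogates,
                           p_value=p, significant=significant)


def time_of_day_baseline(train_event_times, grid_times,
                         n_training_days: float) -> np.ndarray:
    """Clock-time baseline: hourly likelihood from the training events'
    time-of-day histogram (count in the clock hour / training days)."""
    if n_training_days <= 0:
        raise ValueError("n_training_days must be positive")
    ev = np.asarray(train_event_times, dtype="datetime64[ns]")
    if ev.size == 0:
        raise ValueError("time-of-day baseline requires at least one training event")
    hours = ev.astype("datetime64[h]").astype("int64") % 24
    counts = np.bincount(hours, minlength=24)
    grid = np.asarray(grid_times, dtype="datetime64[ns]")
    grid_hours = grid.astype("datetime64[h]").astype("int64") % 24
    return counts[grid_hours] / n_training_days


@dataclass
class EvaluationReport:
    """Scores of one pseudo-prospective forecast series."""

    auc: float
    bss: float
    sensitivity: float
    time_in_high: float
    surrogate_p: float
    significant: bool
    n_events: int
    resolution: str

    def to_dict(self) -> dict:
        return {"auc": self.auc, "bss": self.bss,
                "sensitivity": self.sensitivity,
                "time_in_high": self.time_in_high,
                "surrogate_p": self.surrogate_p,
                "significant": self.significant,
                "n_events": self.n_events, "resolution": self.resolution}
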