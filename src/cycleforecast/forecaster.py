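"""Forecast orchestration: training, issuance, walk-forward evaluation.

A model is first trained once the first 10 seizures have been reported
(training cut-off: midnight ending that day). Each issuance projects all
significant cycles 60 days ahead at hourly resolution, converts projected
phases to likelihoods and risk labels, and is re-issued at midnight after
every reported seizure or 7 days after the last issue, whichever comes
first. Stored segments are concatenated chronologically into the
pseudo-prospective series that evaluation scores.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .containers import (DAY, HOUR, EventDiary, HeartRateSeries, PhaseSeries,
                         hour_grid, midnight_after)
from .cycles import (DEFAULT_SI_THRESHOLD, detect_event_cycles,
                     detect_hr_cycles, extract_cycle, fill_missing,
                     hilbert_phase, sinusoid_phase)
from .likelihood import (DEFAULT_N_BINS, PhaseLikelihoodModel, classify_risk,
                         combine_likelihoods, estimate_bin_likelihoods,
                         fit_thresholds)
from .projection import AdditiveModel, fit_additive, project_hr_cycle
from . import evaluation

__all__ = [
    "MODALITIES",
    "initial_training_cutoff",
    "ModalityModel",
    "TrainedModels",
    "train",
    "ForecastSegment",
    "issue_forecast",
    "PseudoProspectiveSeries",
    "run_pseudo_prospective",
    "daily_average",
    "select_best",
]

MODALITIES = ("diary", "hr", "combined")
DEFAULT_HORIZON_DAYS = 60.0
DEFAULT_REISSUE_DAYS = 7.0
DEFAULT_TRAINING_EVENTS = 10


def initial_training_cutoff(diary: EventDiary,
                            n_events: int = DEFAULT_TRAINING_EVENTS) -> np.datetime64:
    """Midnight ending the day on which the ``n_events``-th seizure was
    reported (later same-day events fall inside training too)."""
    if len(diary) < n_events:
        raise ValueError(
            f"initial training requires {n_events} events; diary has {len(diary)}")
    return midnight_after(diary.times[n_events - 1])


@dataclass
class ModalityModel:
    """Cycle set, bin likelihoods and thresholds for one data modality."""

    modality: str
    model: PhaseLikelihoodModel
    flat_rate: float
    additive: Optional[AdditiveModel] = None
    reference_time: Optional[np.datetime64] = None

    @property
    def flat(self) -> bool:
        return len(self.model.cycles) == 0

    def to_dict(self) -> dict:
        return {"modality": self.modality, "model": self.model.to_dict(),
                "flat_rate": self.flat_rate,
                "additive": self.additive.to_dict() if self.additive else None,
                "reference_time": str(self.reference_time)}

    @classmethod
    def from_dict(cls, d: dict) -> "ModalityModel":
        return cls(modality=d["modality"],
                   model=PhaseLikelihoodModel.from_dict(d["model"]),
                   flat_rate=d["flat_rate"],
                   additive=AdditiveModel.from_dict(d["additive"])
                   if d.get("additive") else None,
                   reference_time=np.datetime64(d["reference_time"], "ns"))


@dataclass
class TrainedModels:
    """Per-modality models fitted on data up to ``cutoff``."""

    record_start: np.datetime64
    cutoff: np.datetime64
    n_training_events: int
    models: dict

    def __getitem__(self, modality: str) -> ModalityModel:
        return self.models[modality]

    def to_dict(self) -> dict:
        return {"record_start": str(self.record_start),
                "cutoff": str(self.cutoff),
                "n_training_events": self.n_training_events,
                "models": {k: m.to_dict() for k, m in self.models.items()}}

    @classmethod
    def from_dict(cls, d: dict) -> "TrainedModels":
        return cls(record_start=np.datetime64(d["record_start"], "ns"),
                   cutoff=np.datetime64(d["cutoff"], "ns"),
                   n_training_events=d["n_training_events"],
                   models={k: ModalityModel.from_dict(m)
                           for k, m in d["models"].items()})


def _training_series(model: PhaseLikelihoodModel, phases: np.ndarray,
                     flat_rate: float, n_hours: int) -> np.ndarray:
    if len(model.cycles) == 0:
        return np.full(n_hours, flat_rate)
    return model.likelihood_from_phases(phases)


def train(hr: HeartRateSeries, diary: EventDiary, cutoff, *,
          modalities=MODALITIES,
          si_threshold: float = DEFAULT_SI_THRESHOLD,
          n_bins: int = DEFAULT_N_BINS,
          significance: float = 0.95,
          min_training_events: int = DEFAULT_TRAINING_EVENTS) -> TrainedModels:
    """Fit cycle, likelihood and threshold models on data up to ``cutoff``.

    HR cycles are re-detected on the heart rate up to the cutoff, diary
    cycles on the events up to the cutoff; bin likelihoods and risk
    thresholds are fitted on the training span only.
    """
    cutoff = np.datetime64(cutoff, "ns")
    events_train = diary.until(cutoff)
    if len(events_train) < min_training_events:
        raise ValueError(
            f"only {len(events_train)} events at cutoff {cutoff}; "
            f"at least {min_training_events} required - use a later cutoff")
    record_start = hr.start_time
    grid = hour_grid(record_start, cutoff)
    if grid.size == 0:
        raise ValueError("empty training window")
    ev_mask = evaluation.step_event_labels(grid, events_train.times)
    flat_rate = len(events_train) / grid.size
    span_days = float((cutoff - record_start).astype("int64") / 86_400e9)

    models: dict[str, ModalityModel] = {}
    series: dict[str, np.ndarray] = {}

    if "diary" in modalities or "combined" in modalities:
        cycles = detect_event_cycles(events_train, span_days, si_threshold,
                                     reference_time=record_start)
        phases = np.vstack([sinusoid_phase(grid, c.period, record_start).phase
                            for c in cycles]) if cycles else np.empty((0, grid.size))
        bins = [estimate_bin_likelihoods(
            PhaseSeries(grid, phases[k]), events_train, n_bins)
            for k in range(len(cycles))]
        plm = PhaseLikelihoodModel(cycles=cycles, bin_likelihoods=bins,
                                   n_bins=n_bins)
        s = _training_series(plm, phases, flat_rate, grid.size)
        plm.thresholds = fit_thresholds(s, ev_mask)
        models["diary"] = ModalityModel("diary", plm, flat_rate,
                                        reference_time=record_start)
        series["diary"] = s

    if "hr" in modalities or "combined" in modalities:
        hr_train = hr.slice_until(cutoff)
        cycles, bins, phase_rows, additive = [], [], [], None
        if hr_train.n > 0 and not hr_train.missing_mask.all():
            filled = fill_missing(hr_train)
            cycles = detect_hr_cycles(filled, significance)
            if cycles:
                additive = fit_additive(filled, [c.period for c in cycles])
            for c in cycles:
                sig = extract_cycle(filled, c)
                ph = hilbert_phase(sig, filled.start_time, step=filled.step)
                phase_rows.append(ph.phase_at(grid))
        phases = np.vstack(phase_rows) if phase_rows else np.empty((0, grid.size))
        bins = [estimate_bin_likelihoods(
            PhaseSeries(grid, phases[k]), events_train, n_bins)
            for k in range(len(cycles))]
        plm = PhaseLikelihoodModel(cycles=cycles, bin_likelihoods=bins,
                                   n_bins=n_bins)
        s = _training_series(plm, phases, flat_rate, grid.size)
        plm.thresholds = fit_thresholds(s, ev_mask)
        models["hr"] = ModalityModel("hr", plm, flat_rate, additive=additive,
                                     reference_time=record_start)
        series["hr"] = s

    if "combined" in modalities:
        combined = combine_likelihoods(np.vstack([series["hr"], series["diary"]]))
        thr = fit_thresholds(np.asarray(combined), ev_mask)
        plm = PhaseLikelihoodModel(cycles=[], bin_likelihoods=[], n_bins=n_bins,
                                   thresholds=thr)
        models["combined"] = ModalityModel("combined", plm, flat_rate,
                                           reference_time=record_start)

    return TrainedModels(record_start=record_start, cutoff=cutoff,
                         n_training_events=len(events_train), models=models)


@dataclass
class ForecastSegment:
    """One issued forecast: hourly likelihood and risk over the horizon."""

    issue_time: np.datetime64
    times: np.ndarray
    likelihood: np.ndarray
    risk: np.ndarray
    modality: str
    flat: bool = False


def _modality_likelihood(models: TrainedModels, grid: np.ndarray,
                         modality: str) -> tuple[np.ndarray, bool]:
    if modality == "combined":
        p_hr, f_hr = _modality_likelihood(models, grid, "hr")
        p_diary, f_diary = _modality_likelihood(models, grid, "diary")
        return np.asarray(combine_likelihoods(np.vstack([p_hr, p_diary]))), \
            f_hr and f_diary
    mm = models[modality]
    cycles = mm.model.cycles
    rows = []
    if modality == "diary":
        for c in cycles:
            rows.append(sinusoid_phase(grid, c.period, mm.reference_time).phase)
        keep = list(range(len(cycles)))
    else:
        keep = []
        horizon_days = grid.size / 24.0
        for k, c in enumerate(cycles):
            proj = project_hr_cycle(mm.additive, c, horizon_days,
                                    issue_time=grid[0])
            if proj.degenerate:
                continue
            rows.append(proj.phase.phase_at(grid))
            keep.append(k)
    if not rows:
        return np.full(grid.size, mm.flat_rate), True
    sub = PhaseLikelihoodModel(
        cycles=[cycles[k] for k in keep],
        bin_likelihoods=[mm.model.bin_likelihoods[k] for k in keep],
        n_bins=mm.model.n_bins)
    return np.asarray(sub.likelihood_from_phases(np.vstack(rows))), False


def issue_forecast(models: TrainedModels, issue_time,
                   horizon_days: float = DEFAULT_HORIZON_DAYS,
                   modality: str = "combined") -> ForecastSegment:
    """Issue one forecast segment from ``issue_time`` over the horizon.

    Per future hour each cycle's projected phase bin supplies its bin
    likelihood; cycles are combined with the logit rule and labelled with
    the modality's fitted thresholds. A modality without significant cycles
    yields a flat segment at the training event rate, flagged.
    """
    if modality not in MODALITIES:
        raise ValueError(f"unknown modality {modality!r}")
    issue_time = np.datetime64(issue_time, "ns")
    if issue_time < models.cutoff:
        raise ValueError("cannot issue a forecast before the training cutoff")
    n = int(round(horizon_days * 24))
    grid = issue_time + np.arange(n) * HOUR
    if n == 0:
        return ForecastSegment(issue_time, grid, np.empty(0),
                               np.empty(0, dtype=object), modality)
    p, flat = _modality_likelihood(models, grid, modality)
    risk = classify_risk(p, models[modality].model.thresholds)
    return ForecastSegment(issue_time, grid, p, np.asarray(risk), modality,
                           flat=flat)


@dataclass
class PseudoProspectiveSeries:
    """Chronological concatenation of reissued forecasts.

    ``provenance[i]`` is the issue time of the segment that supplied hour
    ``i``; strict causality demands ``provenance[i] <= times[i]``.
    """

    times: np.ndarray
    likelihood: np.ndarray
    risk: np.ndarray
    provenance: np.ndarray
    modality: str
    training_cutoff: np.datetime64
    issue_log: list = field(default_factory=list)

    @property
    def n(self) -> int:
        return self.times.size


def _issue_times(diary: EventDiary, start: np.datetime64, end: np.datetime64,
                 reissue_interval_days: float) -> list[np.datetime64]:
    step = np.timedelta64(int(round(reissue_interval_days * 86_400e9)), "ns")
    issues = [start]
    current = start
    while True:
        later = diary.times[diary.times >= current]
        candidates = [current + step]
        if later.size:
            candidates.append(midnight_after(later[0]))
        nxt = min(candidates)
        if nxt >= end:
            break
        issues.append(nxt)
        current = nxt
    return issues


def run_pseudo_prospective(hr: HeartRateSeries, diary: EventDiary,
                           initial_cutoff=None, end_time=None,
                           modality: str = "combined", *,
                           horizon_days: float = DEFAULT_HORIZON_DAYS,
                           reissue_interval_days: float = DEFAULT_REISSUE_DAYS,
                           min_training_events: int = DEFAULT_TRAINING_EVENTS,
                           si_threshold: float = DEFAULT_SI_THRESHOLD,
                           n_bins: int = DEFAULT_N_BINS,
                           significance: float = 0.95,
                           return_last_models: bool = False):
    """Walk-forward evaluation: retrain and reissue at every reported
    seizure (midnight after it) and at 7-day intervals since the last
    issue; every hour of the evaluation span takes its likelihood from the
    most recent issued segment."""
    if initial_cutoff is None:
        initial_cutoff = initial_training_cutoff(diary, min_training_events)
    initial_cutoff = np.datetime64(initial_cutoff, "ns")
    if end_time is None:
        end_time = hr.end_time
    end_time = np.datetime64(end_time, "ns")
    grid = hour_grid(initial_cutoff, end_time)
    if grid.size == 0:
        raise ValueError("empty evaluation span")
    likelihood = np.empty(grid.size)
    risk = np.empty(grid.size, dtype=object)
    provenance = np.empty(grid.size, dtype="datetime64[ns]")
    mods = MODALITIES if modality == "combined" else (modality,)
    issues = _issue_times(diary, initial_cutoff, end_time,
                          reissue_interval_days)
    issue_log = []
    last_models = None
    for k, issue in enumerate(issues):
        seg_end = issues[k + 1] if k + 1 < len(issues) else end_time
        models = train(hr, diary, issue, modalities=mods,
                       si_threshold=si_threshold, n_bins=n_bins,
                       significance=significance,
                       min_training_events=min_training_events)
        horizon = max(horizon_days,
                      (seg_end - issue).astype("int64") / 86_400e9)
        seg = issue_forecast(models, issue, horizon, modality)
        sel = (grid >= issue) & (grid < seg_end)
        idx = ((grid[sel] - seg.times[0]) // HOUR).astype("int64")
        likelihood[sel] = seg.likelihood[idx]
        risk[sel] = seg.risk[idx]
        provenance[sel] = issue
        issue_log.append({
            "issue_time": str(issue),
            "n_training_events": models.n_training_events,
            "n_cycles": len(models[modality].model.cycles)
            if modality != "combined" else
            len(models["hr"].model.cycles) + len(models["diary"].model.cycles),
            "flat": bool(seg.flat),
        })
        last_models = models
    series = PseudoProspectiveSeries(
        times=grid, likelihood=likelihood, risk=np.asarray(risk, dtype=object),
        provenance=provenance, modality=modality,
        training_cutoff=initial_cutoff, issue_log=issue_log)
    if return_last_models:
        return series, last_models
    return series


def daily_average(series: PseudoProspectiveSeries):
    """Daily forecast: arithmetic mean of the 24 hourly likelihoods per
    calendar day; partial first/last days are excluded with a warning."""
    days = series.times.astype("datetime64[D]")
    uniq, start_idx, counts = np.unique(days, return_index=True,
                                        return_counts=True)
    full = counts == 24
    if not full.all():
        warnings.warn(f"excluding {int((~full).sum())} partial day(s) from the "
                      "daily forecast")
    means = np.array([series.likelihood[i:i + 24].mean()
                      for i, keep in zip(start_idx, full) if keep])
    return uniq[full].astype("datetime64[ns]"), means


def select_best(series_by_modality: dict, events: EventDiary) -> str:
    """Modality with the highest evaluation AUC; ties prefer fewer
    modalities (diary < hr < combined)."""
    best, best_auc = None, -np.inf
    for modality in ("diary", "hr", "combined"):
        if modality not in series_by_modality:
            continue
        s = series_by_modality[modality]
        labels = evaluation.step_event_labels(s.times, events.times)
        if not labels.any():
            raise ValueError("no events in the evaluation span")
        auc = evaluation.roc_auc(s.likelihood, labels)
        if auc > best_auc:
            best, best_auc = modality, auc
    if best is None:
        raise ValueError("no modality series supplied")
    return best
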