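"""Readers, writers, run configuration and the end-to-end pipeline.

Interchange formats are plain CSV with ISO-8601 UTC timestamps:

* heart rate: header ``timestamp,bpm``; one row per 5-minute sample, empty
  ``bpm`` field for a missing sample;
* diary: header ``timestamp``; one row per reported event.

Models and evaluation reports are serialised to JSON so a forecast can be
re-issued without refitting.
"""
from __future__ import annotations

import hashlib
import json
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from .containers import HR_STEP, EventDiary, HeartRateSeries, floor_time
from . import evaluation, forecaster
from .forecaster import (MODALITIES, PseudoProspectiveSeries, daily_average,
                         initial_training_cutoff, run_pseudo_prospective,
                         select_best)

__all__ = [
    "read_hr_csv", "write_hr_csv", "read_diary_csv", "write_diary_csv",
    "RunConfig", "run_pipeline",
]


def _parse_timestamps(raw: pd.Series, path) -> np.ndarray:
    parsed = pd.to_datetime(raw, utc=True, errors="coerce", format="ISO8601")
    bad = parsed.isna() & raw.notna()
    if bad.any():
        line = int(bad.idxmax()) + 2  # header line + 1-based
        raise ValueError(f"{path}: unparseable timestamp on line {line}: "
                         f"{raw[bad.idxmax()]!r}")
    if parsed.isna().any():
        line = int(parsed.isna().idxmax()) + 2
        raise ValueError(f"{path}: missing timestamp on line {line}")
    return parsed.dt.tz_localize(None).to_numpy(dtype="datetime64[ns]")


def read_hr_csv(path) -> HeartRateSeries:
    """Read a heart-rate CSV onto the uniform 5-minute grid.

    Timestamps are snapped (floored) to the grid; duplicate slots are
    averaged with a warning; grid slots with no row, or an empty ``bpm``
    field, are marked missing.
    """
    df = pd.read_csv(path, dtype={"bpm": float}, float_precision="round_trip")
    if list(df.columns) != ["timestamp", "bpm"]:
        raise ValueError(f"{path}: expected header 'timestamp,bpm'")
    times = _parse_timestamps(df["timestamp"], path)
    bpm = df["bpm"].to_numpy()
    snapped = np.array([floor_time(t, HR_STEP) for t in times],
                       dtype="datetime64[ns]")
    if snapped.size == 0:
        raise ValueError(f"{path}: empty heart-rate file")
    start = snapped.min()
    n = int((snapped.max() - start) // HR_STEP) + 1
    values = np.full(n, np.nan)
    counts = np.zeros(n)
    idx = ((snapped - start) // HR_STEP).astype("int64")
    if np.unique(idx[~np.isnan(bpm)]).size < np.count_nonzero(~np.isnan(bpm)):
        warnings.warn(f"{path}: duplicate timestamps averaged")
    for i, v in zip(idx, bpm):
        if np.isnan(v):
            continue
        if counts[i] == 0:
            values[i] = v
        else:
            values[i] += v
        counts[i] += 1
    nonzero = counts > 0
    values[nonzero] /= counts[nonzero]
    mask = ~nonzero
    values[mask] = 0.0
    return HeartRateSeries(start_time=start, values=values, missing_mask=mask)


def write_hr_csv(hr: HeartRateSeries, path) -> None:
    times = hr.times
    with open(path, "w") as fh:
        fh.write("timestamp,bpm\n")
        for t, v, m in zip(times, hr.values, hr.missing_mask):
            stamp = np.datetime_as_string(t.astype("datetime64[s]")) + "Z"
            fh.write(f"{stamp},\n" if m else f"{stamp},{float(v)!r}\n")


def read_diary_csv(path) -> EventDiary:
    """Read an event diary CSV; output is sorted, exact duplicates kept."""
    df = pd.read_csv(path)
    if list(df.columns) != ["timestamp"]:
        raise ValueError(f"{path}: expected header 'timestamp'")
    if len(df) == 0:
        return EventDiary(np.empty(0, dtype="datetime64[ns]"))
    return EventDiary(_parse_timestamps(df["timestamp"], path))


def write_diary_csv(diary: EventDiary, path) -> None:
    with open(path, "w") as fh:
        fh.write("timestamp\n")
        for t in diary.times:
            fh.write(np.datetime_as_string(t.astype("datetime64[s]")) + "Z\n")


@dataclass
class RunConfig:
    """Pipeline configuration; defaults are the method's standard constants."""

    hr_csv: str = ""
    diary_csv: str = ""
    si_threshold: float = 0.3
    n_bins: int = 18
    horizon_days: float = 60.0
    reissue_interval_days: float = 7.0
    n_training_events: int = 10
    surrogates: int = 200
    significance: float = 0.95
    seed: int = 0
    modalities: Sequence[str] = MODALITIES
    resolutions: Sequence[str] = ("hourly", "daily")

    def __post_init__(self):
        if not 0.0 <= self.si_threshold <= 1.0:
            raise ValueError("si_threshold must lie in [0, 1]")
        if self.n_bins < 1:
            raise ValueError("n_bins must be a positive count")
        if self.horizon_days <= 0:
            raise ValueError("horizon_days must be positive")
        if self.reissue_interval_days <= 0:
            raise ValueError("reissue_interval_days must be positive")
        if self.n_training_events < 1:
            raise ValueError("n_training_events must be a positive count")
        if self.surrogates < 1:
            raise ValueError("surrogates must be a positive count")
        if not 0.0 < self.significance < 1.0:
            raise ValueError("significance must lie in (0, 1)")
        bad = set(self.modalities) - set(MODALITIES)
        if bad:
            raise ValueError(f"unknown modalities: {sorted(bad)}")
        bad = set(self.resolutions) - {"hourly", "daily"}
        if bad:
            raise ValueError(f"unknown resolutions: {sorted(bad)}")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = set(cls.__dataclass_fields__)
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config fields: {sorted(unknown)}")
        return cls(**raw)

    def digest(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def _write_series_csv(series: PseudoProspectiveSeries, path) -> None:
    with open(path, "w") as fh:
        fh.write("timestamp,likelihood,risk\n")
        for t, p, r in zip(series.times, series.likelihood, series.risk):
            stamp = np.datetime_as_string(t.astype("datetime64[s]")) + "Z"
            fh.write(f"{stamp},{float(p)!r},{r}\n")


def _write_daily_csv(days, values, path) -> None:
    with open(path, "w") as fh:
        fh.write("date,likelihood\n")
        for d, p in zip(days.astype("datetime64[D]"), values):
            fh.write(f"{d},{float(p)!r}\n")


def _evaluate(series: PseudoProspectiveSeries, diary: EventDiary,
              resolution: str, n_surrogates: int, seed: int
              ) -> evaluation.EvaluationReport:
    if resolution == "hourly":
        times, L, risk = series.times, series.likelihood, series.risk
    else:
        times, L = daily_average(series)
        risk = None
    labels = evaluation.step_event_labels(times, diary.times)
    auc = evaluation.roc_auc(L, labels)
    bss = evaluation.brier_skill_score(L, labels)
    if risk is not None:
        sens, tih = evaluation.operating_point(risk, labels)
    else:
        sens, tih = float("nan"), float("nan")
    surr = evaluation.surrogate_test(L, labels, n_shuffles=n_surrogates,
                                     seed=seed)
    return evaluation.EvaluationReport(
        auc=auc, bss=bss, sensitivity=sens, time_in_high=tih,
        surrogate_p=surr.p_value, significant=surr.significant,
        n_events=int(labels.sum()), resolution=resolution)


def run_pipeline(config: RunConfig, out_dir) -> dict:
    """Run the full pseudo-prospective pipeline and write all artifacts.

    Produces, per modality: hourly and daily forecast CSVs, an evaluation
    JSON entry per resolution; plus the final model JSON, a cycles report,
    an issuance log (JSONL) and a run log with the config hash.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    hr = read_hr_csv(config.hr_csv)
    diary = read_diary_csv(config.diary_csv)
    cutoff = initial_training_cutoff(diary, config.n_training_events)
    results: dict = {"config_digest": config.digest(), "modalities": {}}
    series_by_modality = {}
    final_models = None
    for modality in config.modalities:
        series, models = run_pseudo_prospective(
            hr, diary, cutoff, modality=modality,
            horizon_days=config.horizon_days,
            reissue_interval_days=config.reissue_interval_days,
            min_training_events=config.n_training_events,
            si_threshold=config.si_threshold,
            significance=config.significance, n_bins=config.n_bins,
            return_last_models=True)
        series_by_modality[modality] = series
        final_models = models
        _write_series_csv(series, out / f"forecast_hourly_{modality}.csv")
        days, daily = daily_average(series)
        _write_daily_csv(days, daily, out / f"forecast_daily_{modality}.csv")
        with open(out / f"issuance_log_{modality}.jsonl", "w") as fh:
            for entry in series.issue_log:
                fh.write(json.dumps(entry) + "\n")
        reports = {}
        for resolution in config.resolutions:
            rep = _evaluate(series, diary, resolution, config.surrogates,
                            config.seed)
            reports[resolution] = rep.to_dict()
        results["modalities"][modality] = reports
    results["best_modality"] = select_best(series_by_modality, diary)
    (out / "evaluation.json").write_text(json.dumps(results, indent=2) + "\n")
    if final_models is not None:
        (out / "model.json").write_text(
            json.dumps(final_models.to_dict(), indent=2) + "\n")
        cycles_report = {
            m: [c.to_dict() for c in final_models[m].model.cycles]
            for m in final_models.models}
        (out / "cycles.json").write_text(
            json.dumps(cycles_report, indent=2) + "\n")
    run_log = {"config": {k: (list(v) if isinstance(v, tuple) else v)
                          for k, v in asdict(config).items()},
               "config_digest": config.digest(),
               "initial_cutoff": str(cutoff),
               "n_events": int(len(diary))}
    (out / "run_log.json").write_text(json.dumps(run_log, indent=2) + "\n")
    return results
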