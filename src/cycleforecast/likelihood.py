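"""Phase-binned seizure likelihood estimation and combination.

For each significant cycle, the phase circle (-pi, pi] is divided into 18
equal bins and the likelihood of a seizure in a bin is the number of event
hours observed in that bin divided by the number of hours the bin was
presented. Likelihoods from several cycles (and from the heart-rate and
diary modalities) are combined through a logit model: the geometric mean of
the odds, mapped back to a probability. Two cutoffs then classify each
combined likelihood into low / medium / high risk.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional

import numpy as np

from .containers import CycleSpec, EventDiary, PhaseSeries

__all__ = [
    "DEFAULT_N_BINS",
    "bin_edges",
    "phase_bin",
    "estimate_bin_likelihoods",
    "combine_likelihoods",
    "RiskThresholds",
    "fit_thresholds",
    "classify_risk",
    "PhaseLikelihoodModel",
]

DEFAULT_N_BINS = 18
#: clipping bound applied before the odds transform (p in {0,1} has no odds)
ODDS_EPS = 1e-4

RISK_LEVELS = ("low", "medium", "high")


def bin_edges(n_bins: int = DEFAULT_N_BINS) -> np.ndarray:
    return np.linspace(-np.pi, np.pi, n_bins + 1)


def phase_bin(phase, n_bins: int = DEFAULT_N_BINS) -> np.ndarray:
    """Index of the half-open phase bin (edge_i, edge_{i+1}] for each phase."""
    edges = bin_edges(n_bins)
    idx = np.searchsorted(edges, np.asarray(phase, dtype=float), side="left") - 1
    return np.clip(idx, 0, n_bins - 1)


def event_hours(events: EventDiary) -> np.ndarray:
    """Distinct clock hours containing at least one event."""
    floored = (events.times.astype("datetime64[h]")).astype("datetime64[ns]")
    return np.unique(floored)


def estimate_bin_likelihoods(phase: PhaseSeries, events: EventDiary,
                             n_bins: int = DEFAULT_N_BINS) -> np.ndarray:
    """Per-bin seizure likelihood for one cycle.

    For bin b: p_b = (# event hours with phase in b) / (# hours with phase
    in b); bins never presented get p_b = 0. ``phase`` must be an hourly
    series covering every event time.
    """
    if len(events) == 0:
        warnings.warn("no events in training window; all-zero likelihood model")
        return np.zeros(n_bins)
    visits = np.bincount(phase_bin(phase.phase, n_bins), minlength=n_bins)
    ev_hours = event_hours(events)
    ev_phase = phase.phase_at(ev_hours)
    hits = np.bincount(phase_bin(ev_phase, n_bins), minlength=n_bins)
    with np.errstate(invalid="ignore", divide="ignore"):
        p = np.where(visits > 0, hits / np.maximum(visits, 1), 0.0)
    return p


def combine_likelihoods(p_list, eps: float = ODDS_EPS):
    """Combine likelihoods across cycles via the logit model.

    p = prod_i (p_i / (1 - p_i))^(1/n);  p_s = p / (1 + p).

    Equivalently the arithmetic mean of log-odds mapped through the
    logistic function; order-invariant and idempotent for equal inputs.
    Accepts a 1-D sequence (returns a scalar) or a 2-D array combining
    along axis 0 (returns a per-column array).
    """
    p = np.asarray(p_list, dtype=float)
    if p.size == 0:
        raise ValueError("combine_likelihoods requires at least one likelihood")
    p = np.clip(p, eps, 1.0 - eps)
    log_odds = np.log(p) - np.log1p(-p)
    m = log_odds.mean(axis=0)
    out = 1.0 / (1.0 + np.exp(-m))
    if np.ndim(out) == 0:
        return float(out)
    return out


@dataclass
class RiskThresholds:
    """Medium/high cutoffs on the combined likelihood.

    ``strict`` records whether the seizure-count ordering criterion was met
    with strict inequalities; ``criterion2_met`` whether time-in-low
    exceeded time-in-high; ``degenerate`` flags a constant training series
    (everything labelled low).
    """

    medium_cutoff: float
    high_cutoff: float
    strict: bool = True
    criterion2_met: bool = True
    degenerate: bool = False

    def __post_init__(self):
        if not self.medium_cutoff <= self.high_cutoff:
            raise ValueError("medium_cutoff must not exceed high_cutoff")

    def to_dict(self) -> dict:
        return {"medium_cutoff": self.medium_cutoff,
                "high_cutoff": self.high_cutoff, "strict": self.strict,
                "criterion2_met": self.criterion2_met,
                "degenerate": self.degenerate}

    @classmethod
    def from_dict(cls, d: dict) -> "RiskThresholds":
        return cls(**d)


def fit_thresholds(likelihood_series, event_mask) -> RiskThresholds:
    """Grid-search the medium/high cutoffs over training-series percentiles.

    Criterion 1 (seizures in high > medium > low risk) is imposed first,
    relaxing strict to non-strict ordering only if no pair qualifies; among
    qualifying pairs the one maximising (time in low - time in high) is
    chosen, breaking ties toward lower time-in-high. A constant series
    yields degenerate all-low thresholds with a warning.
    """
    L = np.asarray(likelihood_series, dtype=float)
    ev = np.asarray(event_mask, dtype=bool)
    if L.shape != ev.shape:
        raise ValueError("likelihood series and event mask lengths differ")
    n = L.size
    if n == 0:
        raise ValueError("empty likelihood series")
    if np.all(L == L[0]):
        warnings.warn("constant likelihood series; degenerate thresholds")
        c = float(min(1.0, L[0] + 1.0))
        return RiskThresholds(c, c, strict=False, criterion2_met=False,
                              degenerate=True)
    cand = np.unique(np.percentile(L, np.arange(101)))
    ls = np.sort(L)
    es = np.sort(L[ev])
    ne = es.size
    time_ge = n - np.searchsorted(ls, cand, side="left")
    sz_ge = ne - np.searchsorted(es, cand, side="left")
    # rows i: medium cutoff; cols j: high cutoff (cand ascending => i <= j)
    szh = sz_ge[None, :]
    szm = sz_ge[:, None] - sz_ge[None, :]
    szl = ne - sz_ge[:, None]
    th = time_ge[None, :]
    tl = n - time_ge[:, None]
    valid = np.triu(np.ones((cand.size, cand.size), dtype=bool))
    strict = True
    ok = valid & (szh > szm) & (szm > szl)
    if not ok.any():
        strict = False
        ok = valid & (szh >= szm) & (szm >= szl)
    obj = np.where(ok, (tl - th).astype(float), -np.inf)
    best = obj.max()
    ties = np.argwhere(obj == best)
    # tie-break: lower time-in-high, then lowest cutoffs (deterministic)
    th_at = np.broadcast_to(th, obj.shape)
    order = np.lexsort((ties[:, 1], ties[:, 0],
                        th_at[ties[:, 0], ties[:, 1]]))
    i, j = ties[order[0]]
    return RiskThresholds(float(cand[i]), float(cand[j]), strict=strict,
                          criterion2_met=bool(best > 0))


def classify_risk(likelihood, thresholds: RiskThresholds):
    """Label likelihoods: low (< medium cutoff), medium ([medium, high)),
    high (>= high cutoff)."""
    L = np.asarray(likelihood, dtype=float)
    labels = np.where(L >= thresholds.high_cutoff, "high",
                      np.where(L >= thresholds.medium_cutoff, "medium", "low"))
    if labels.ndim == 0:
        return str(labels)
    return labels


@dataclass
class PhaseLikelihoodModel:
    """Per-cycle 18-bin likelihoods plus the logit combination rule."""

    cycles: list
    bin_likelihoods: list
    n_bins: int = DEFAULT_N_BINS
    thresholds: Optional[RiskThresholds] = None

    def __post_init__(self):
        if len(self.cycles) != len(self.bin_likelihoods):
            raise ValueError("one bin-likelihood table per cycle required")
        self.bin_likelihoods = [np.asarray(b, dtype=float)
                                for b in self.bin_likelihoods]
        for b in self.bin_likelihoods:
            if b.size != self.n_bins:
                raise ValueError(f"expected {self.n_bins} bins, got {b.size}")
            if np.any(b < 0) or np.any(b > 1):
                raise ValueError("bin likelihoods must lie in [0, 1]")

    def likelihood_from_phases(self, phases: np.ndarray) -> np.ndarray:
        """Combined likelihood per time step from a (n_cycles, T) phase array."""
        phases = np.atleast_2d(np.asarray(phases, dtype=float))
        if phases.shape[0] != len(self.cycles):
            raise ValueError("phase rows must match the number of cycles")
        per_cycle = np.vstack([
            self.bin_likelihoods[k][phase_bin(phases[k], self.n_bins)]
            for k in range(len(self.cycles))])
        return np.asarray(combine_likelihoods(per_cycle))

    def to_dict(self) -> dict:
        return {
            "cycles": [c.to_dict() for c in self.cycles],
            "bin_likelihoods": [b.tolist() for b in self.bin_likelihoods],
            "n_bins": self.n_bins,
            "bin_edges": bin_edges(self.n_bins).tolist(),
            "thresholds": self.thresholds.to_dict() if self.thresholds else None,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "PhaseLikelihoodModel":
        thr = d.get("thresholds")
        return cls(cycles=[CycleSpec.from_dict(c) for c in d["cycles"]],
                   bin_likelihoods=[np.asarray(b) for b in d["bin_likelihoods"]],
                   n_bins=d.get("n_bins", DEFAULT_N_BINS),
                   thresholds=RiskThresholds.from_dict(thr) if thr else None)
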