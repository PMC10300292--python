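# Methods

This note documents the models, numerical choices and limitations of
`cycleforecast` — what each stage assumes, which knobs matter, and what the
synthetic-data tests do and do not establish about real recordings.

## Data model

Heart rate is a uniform 5-minute grid of BPM samples with a boolean
missing-mask (device non-wear); the diary is an ordered list of reported
event timestamps. All timestamps are UTC; forecast hours are labelled by
their start (an event at 13:42 belongs to hour 13:00). Missing HR samples
are replaced by the training-period mean before any spectral analysis —
constant filling adds no spurious periodicity, at the cost of damping true
cycle amplitude in proportion to the gap fraction.

## Cycle detection

**Heart rate.** The gap-filled series is averaged to hourly resolution
(the periods of interest are ≥ 1 day; this is purely a cost optimisation),
z-scored, and transformed with an FFT-based Morlet continuous wavelet
transform (nondimensional frequency ω₀ = 6, 24 voices per octave, smallest
scale 2 h, largest period half the record). Significance of the global
(time-averaged) spectrum is assessed against the theoretical spectrum of an
AR(1) background whose lag-1 autocorrelation is estimated from the series,
with a chi-square test whose degrees of freedom grow with the number of
independent wavelet samples per scale (decorrelation factor 2.32 for
Morlet); the default confidence is 95%. Detected cycles are local maxima
of the global power above that curve; peak periods are refined by
quadratic interpolation in log-scale (the raw scale grid is ~3% coarse at
28 days), near-duplicates within one scale step are merged keeping the
higher power, and periods above half the record are discarded. On white
noise this procedure averages roughly one spurious peak per record at 95%
confidence, consistent with a pointwise 5% test across a few dozen
effectively independent scales.

**Diary.** Candidate periods 1.0, 1.5, …, min(70, span/2) days are scanned;
for each, event phases come from a fixed sinusoid referenced to the start
of the training record, and the synchronization index SI (modulus of the
mean unit phasor — the modulus is essential for SI ∈ [0, 1]) is compared
with the inclusion threshold 0.3. Contiguous runs of passing candidates
are merged to their maximum-SI member; genuinely separate harmonic peaks
(e.g. the 7-day harmonic of a 14-day von Mises locking, whose SI is
I₂(κ)/I₀(κ)) are retained as distinct cycles, which is deliberate: they
carry real phase information. Events with identical timestamps each
contribute one phase term.

**Filtering and phase.** Cycles are extracted on the native 5-minute grid
with a zero-phase (forward-backward) second-order Butterworth bandpass at
period × (1 ± 0.3), applied to the z-scored series with reflection padding
of one upper-band length per side; instantaneous phase is the analytic
signal angle, unwrapped, interpolated to whole clock hours and wrapped to
(−π, π]. Edge transients contaminate roughly two cycle periods at each end
of a record; interior phase error on a noiseless sinusoid is ~0.01 rad.

## Likelihood model

Eighteen equal phase bins per cycle; a bin's likelihood is (event hours in
bin)/(hours in bin), counted on the hourly grid, with never-visited bins at
zero. Multiple events in one hour count once. Likelihoods are clipped to
[10⁻⁴, 1 − 10⁻⁴] before the odds transform (p ∈ {0, 1} has no finite
log-odds) and combined as the geometric mean of odds mapped back to a
probability — permutation-invariant, idempotent for equal inputs, monotone
in each argument.

Risk cutoffs are grid-searched over the deduplicated percentiles of the
training likelihood series. Pairs must order seizure counts high > medium
> low (strict first, relaxed to non-strict only when no strict pair
exists); among qualifying pairs the one maximising (time in low − time in
high) wins, ties broken toward lower time-in-high and then lower cutoffs.
A constant training series yields degenerate all-low thresholds with a
warning. Thresholds are refit whenever the likelihood model is refit.

## Projection

The additive model is fitted by penalised least squares on the
hourly-averaged series: columns are an intercept, a base slope, 25
hinge-function changepoints spread uniformly over the first 80% of the
record (L2 penalty 10 on their slope adjustments), and Fourier terms of
order 3 for the daily, weekly and each detected multidien period plus
order 10 for a yearly term (L2 penalty 0.1 on all seasonal coefficients;
terms longer than the record are dropped with a warning). The native
penalised-least-squares backend is the only one; it reproduces planted
amplitudes within ~5% on clean data and within 15% at SNR 2.

A projected HR cycle is the model's seasonal component for that period,
evaluated analytically from two band-lengths before the fit origin to two
band-lengths past the horizon (so filter and Hilbert transients fall
outside the returned segment), bandpassed at the cycle's band, and phased
with the same Hilbert procedure as observed data — keeping training and
projected phases on one convention. Projected phase error on a noiseless
planted cycle is < 0.03 rad across a 60-day horizon. Diary cycles are
projected exactly by the fixed sinusoid. Trend and holiday-style regressors
never enter the phase computation.

## Forecasting pipeline

Initial training ends at the midnight closing the day of the 10th reported
event (same-day events all fall inside training; membership is strictly
before the cutoff, so an event exactly at midnight belongs to the next
day). Forecasts are issued at the cutoff and re-issued at the earlier of
7 days since the last issue or the midnight after the next reported event;
every issuance re-detects cycles, refits likelihoods and thresholds on data
up to its own cutoff, and projects 60 days of hourly likelihoods per
modality (diary, HR, and their logit combination). Each evaluation hour
takes its value from the most recent issued segment; the stored provenance
makes the strict-causality claim mechanically checkable. Daily forecasts
are the arithmetic mean of the 24 hourly likelihoods per complete calendar
day. The best modality per subject is the one with the highest evaluation
AUC, ties preferring fewer data streams (diary < hr < combined).

## Evaluation

The ROC is time-in-warning style: as the warning threshold sweeps the
forecast values, x is the fraction of all steps at/above threshold and y
the fraction of event steps at/above it; the AUC integrates by trapezoid
through (0,0) and (1,1). Steps are hours (days at daily resolution) and an
event step is any step containing ≥ 1 report. The Brier Skill Score uses a
constant reference at the evaluation-period mean event rate. Surrogate
significance redraws the observed number of event steps uniformly without
replacement 200 times; the forecast is significant when its AUC exceeds
95% of surrogate AUCs, and the reported p-value uses the add-one
convention (1 + #{surrogate ≥ observed})/201. An inter-event-interval
preserving shuffle is not offered; uniform relocation matches the
exchangeability assumption the test needs. The time-of-day baseline maps
the training events' clock-hour histogram (count/training days) onto the
evaluation grid; averaged to daily resolution it is constant, i.e. chance.

Note that at daily resolution the BSS of an hourly-mean likelihood is
systematically penalised: the forecast remains on the per-hour probability
scale (~0.01) while the daily event base rate is an order of magnitude
larger, so daily BSS values can be negative even when daily AUC is high.
The package reports the score as defined rather than recalibrating.

## Synthetic data

The generator emulates the cyclic structure of long wearable recordings:
baseline + Σ Aₖ cos(2πt/Pₖ + φₖ) + AR(1) noise (innovations scaled so the
marginal SD equals `noise_sd`), with `missing_fraction` of samples masked
in contiguous blocks of geometric length (mean 6 h, mimicking non-wear),
and events drawn by thinning a homogeneous rate with a product of von Mises
densities (concentration κ) on the phases of the locking cycles,
renormalised so the expected count is `event_rate × duration`. Defaults
are a 180-day record at 75 BPM baseline with daily/weekly/2-weekly/monthly
cycles (5/3/3/3 BPM), noise SD 5 BPM, 18% missingness, 0.22 events/day
locked to the 14-day cycle at κ = 2 — matching the typical cohort figures
for long-term smartwatch studies (multi-month records, ~82% wear time,
~0.2 reported seizures/day). Everything is reproducible bit-for-bit from
the scenario seed.

What passing tests on this generator do **not** show: robustness to HR
artefacts, non-sinusoidal or drifting cycles, reporting bias with clock-time
structure, or missingness correlated with seizures. In particular, because
planted cycles are pure sinusoids, events locked to an "HR" cycle are
equally visible to the diary scan, so the generator cannot demonstrate
situations where only the HR modality is informative.

## Test problem sizes

Cycle-recovery checks use 120-day records (SNR 1 for the HR spectrum test;
κ = 8, ~30 events for the diary test). End-to-end forecast-skill checks
use 270-day records at 0.22 events/day — a scaled-down version of the
multi-year cohort recordings the method targets — where the hourly AUC
exceeds 0.70 with a significant surrogate test in ≥ 18/20 seeds. Type-I
calibration fixes one unlocked (κ = 0) pseudo-prospective forecast series
and redraws 200 independent null event sets through the surrogate test;
this verifies the test's calibration under exchangeable labels but ignores
the second-order adaptivity of retraining to evaluated events, which a
full re-simulation would capture.

## Known limitations

* Likelihoods are empirical frequencies, not calibrated probabilities;
  forecasts rank risk well before they estimate it well (visible in small
  hourly BSS values).
* The AR(1) red-noise background is estimated from a series that contains
  the very cycles under test, inflating the background near long periods;
  strong multidien cycles still clear it, weak ones near the half-record
  cap may not.
* Thresholds optimise the training criteria exactly as stated; on peaked
  likelihood distributions this favours small high-risk bands (high
  specificity, modest sensitivity).
* Timezone/daylight-saving structure in real diaries is not modelled; all
  arithmetic is UTC.
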