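# cycleforecast

Seizure-risk forecasting from multiday cycles of wearable heart rate and
self-reported seizure diaries.

Many people with epilepsy have seizures that cluster along slow rhythms —
daily, weekly, fortnightly or monthly "multidien" cycles — visible both in
their reported seizure times and in physiological signals such as
smartwatch heart rate (HR). `cycleforecast` implements a cycle-based
forecasting pipeline for researchers working on non-invasive seizure
forecasting: it detects those cycles, converts them into phase-conditioned
seizure likelihoods, projects them up to 60 days ahead, and scores the
resulting forecasts pseudo-prospectively. A synthetic-data generator with
known ground truth makes every stage testable without any patient data.

## Method

**Cycle detection.** HR (5-minute samples, non-wear gaps filled with the
training-mean) is analysed with a continuous Morlet wavelet transform;
significant cycles are peaks of the global (time-averaged) power spectrum
above an AR(1) red-noise background at 95% confidence. Each cycle is
extracted with a zero-phase second-order Butterworth bandpass at
`period × (1 ± 0.3)` and its instantaneous phase obtained from the Hilbert
transform. Diary cycles are found by scanning candidate periods (1–70 d in
0.5 d steps, capped at half the record) and keeping those whose event
phases lock with synchronization index

    SI = | (1/N) Σₙ exp(i θₙ) | ≥ 0.3

where θₙ is the phase of the n-th seizure under a fixed sinusoid of the
candidate period.

**Likelihood model.** The phase circle (−π, π] is split into 18 equal bins;
the seizure likelihood of a bin is the number of event hours observed in it
divided by the number of hours it was presented. Likelihoods pᵢ from
several cycles (and from the HR and diary modalities) are combined with a
logit model,

    p = Πᵢ ( pᵢ / (1 − pᵢ) )^(1/n),   p_s = p / (1 + p),

and two cutoffs — chosen so that seizures concentrate in high > medium >
low risk while time in low exceeds time in high — label each hour low,
medium or high risk.

**Projection and evaluation.** HR cycles are projected with an additive
regression model `y(t) = g(t) + s(t) + ε(t)` (piecewise-linear trend plus
Fourier seasonal terms per period); diary cycles with fixed sinusoids.
Forecasts are issued hourly over a 60-day horizon, retrained at midnight
after every reported seizure or weekly, and concatenated chronologically
into a pseudo-prospective series that is scored with the time-in-warning
ROC/AUC, Brier Skill Score, and a 200-shuffle surrogate significance test,
against a time-of-day baseline.

## Worked example

`examples/02_forecast_and_evaluate.py` simulates a nine-month recording
(0.22 reported seizures/day, phase-locked to a 14-day cycle with von Mises
concentration κ = 8), runs the full walk-forward pipeline on the diary
modality and prints:

```
51 events; trained at 2020-01-31T00:00:00.000000000; 50 forecasts issued over 240 evaluation days
hourly forecast:  AUC 0.84  BSS 0.010  Sens 15%  TiH 3%  surrogate p=0.005
daily forecast:   AUC 0.87  BSS -0.115
time-of-day baseline: hourly AUC 0.46
```

AUC 0.84 means a randomly chosen seizure hour outranks 84% of all hours in
forecast likelihood (0.5 = chance); the surrogate p-value says no random
relocation of the seizures out of 200 matched that skill. The time-of-day
baseline stays at chance because the simulated seizures carry no clock-time
preference. The other examples demonstrate cycle detection against planted
ground truth (`01_simulate_and_detect.py`) and 60-day additive-model cycle
projection (`03_project_cycles.py`).

The same pipeline is available from the shell:

```bash
cycleforecast simulate --config scenario.yaml --out data/
cycleforecast run --hr data/hr.csv --diary data/diary.csv --out results/
```

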