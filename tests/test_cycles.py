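"""Cycle detection, filtering and phase computation."""
import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import cycleforecast as cf
from cycleforecast.containers import CycleSpec, EventDiary, wrap_phase
from cycleforecast.cycles import (band_edges, candidate_periods, compute_si,
                                  detect_event_cycles, detect_hr_cycles,
                                  extract_cycle, fill_missing, hilbert_phase,
                                  sinusoid_phase)
from conftest import T0, make_hr, sinusoid_hr


class TestFillMissing:
    def test_no_gaps_is_identity(self):
        hr = sinusoid_hr(5, 1.0)
        out = fill_missing(hr, 70.0)
        assert np.array_equal(out.values, hr.values)

    def test_gap_filled_with_training_mean(self):
        mask = np.zeros(288, dtype=bool)
        mask[100:112] = True
        hr = make_hr(np.full(288, 65.0), mask=mask)
        out = fill_missing(hr, 70.0)
        assert np.all(out.values[100:112] == 70.0)
        assert np.all(out.values[:100] == 65.0)
        assert np.array_equal(out.missing_mask, mask)  # mask kept as metadata

    def test_all_missing_with_mean_gives_constant(self):
        hr = make_hr(np.zeros(288), mask=np.ones(288, dtype=bool))
        assert np.all(fill_missing(hr, 65.0).values == 65.0)

    def test_all_missing_without_mean_raises(self):
        hr = make_hr(np.zeros(288), mask=np.ones(288, dtype=bool))
        with pytest.raises(ValueError):
            fill_missing(hr)


class TestBandEdges:
    def test_eight_day_cycle_30pct(self):
        low, high = band_edges(8.0, 0.3)
        assert low == pytest.approx(5.6, abs=1e-12)
        assert high == pytest.approx(10.4, abs=1e-12)

    def test_band_collapses_as_fraction_vanishes(self):
        low, high = band_edges(8.0, 1e-9)
        assert low == pytest.approx(8.0, abs=1e-6)
        assert high == pytest.approx(8.0, abs=1e-6)

    @pytest.mark.parametrize("period,frac", [(-1, 0.3), (8, 0.0), (8, 1.0)])
    def test_invalid_inputs_raise(self, period, frac):
        with pytest.raises(ValueError):
            band_edges(period, frac)


class TestCandidatePeriods:
    def test_half_record_cap(self):
        assert candidate_periods(20.0).max() == 10.0

    def test_long_record_caps_at_70(self):
        p = candidate_periods(200.0)
        assert p[0] == 1.0 and p[-1] == 70.0 and p.size == 139

    def test_too_short_record_is_empty(self):
        assert candidate_periods(1.5).size == 0

    def test_step_is_half_day(self):
        assert np.allclose(np.diff(candidate_periods(40.0)), 0.5)


class TestSinusoidPhase:
    def test_reference_and_periodicity(self, t0):
        day = np.timedelta64(1, "D")
        times = np.array([t0, t0 + 7 * day, t0 + int(7 * 24 / 4) * np.timedelta64(1, "h")])
        ph = sinusoid_phase(times, 7.0, t0)
        assert ph.phase[0] == pytest.approx(0.0, abs=1e-12)
        assert ph.phase[1] == pytest.approx(0.0, abs=1e-9)
        assert ph.phase[2] == pytest.approx(np.pi / 2, abs=1e-9)

    def test_phases_wrapped(self, t0):
        times = t0 + np.arange(1000) * np.timedelta64(1, "h")
        ph = sinusoid_phase(times, 3.0, t0)
        assert np.all(ph.phase > -np.pi) and np.all(ph.phase <= np.pi)


class TestComputeSI:
    def test_perfect_locking(self):
        assert compute_si(np.full(10, 1.2)) == pytest.approx(1.0)

    def test_symmetric_cancellation(self):
        assert compute_si([0, np.pi / 2, np.pi, 3 * np.pi / 2]) == \
            pytest.approx(0.0, abs=1e-12)

    def test_three_phase_hand_value(self):
        assert compute_si([0.0, 0.0, np.pi / 2]) == \
            pytest.approx(np.sqrt(5) / 3, abs=1e-12)

    def test_empty_raises(self):
        with pytest.raises(ValueError):
            compute_si([])

    @settings(deadline=None, derandomize=True, max_examples=50)
    @given(st.lists(st.floats(-np.pi, np.pi), min_size=1, max_size=50),
           st.floats(-10, 10))
    def test_invariant_to_global_rotation(self, phases, rot):
        a = compute_si(phases)
        b = compute_si(np.asarray(phases) + rot)
        assert a == pytest.approx(b, abs=1e-9)


class TestHilbertPhase:
    def test_cosine_phase_matches_sinusoid_phase(self, t0):
        n = 56 * 288
        t = np.arange(n) / 288.0
        ph = hilbert_phase(np.cos(2 * np.pi * t / 7.0), t0)
        truth = sinusoid_phase(ph.times, 7.0, t0)
        interior = slice(7 * 24, -7 * 24)
        err = np.abs(wrap_phase(ph.phase[interior] - truth.phase[interior]))
        assert err.max() < 0.05

    def test_sine_lags_quarter_cycle(self, t0):
        n = 56 * 288
        t = np.arange(n) / 288.0
        ph = hilbert_phase(np.sin(2 * np.pi * t / 7.0), t0)
        truth = sinusoid_phase(ph.times, 7.0, t0)
        interior = slice(7 * 24, -7 * 24)
        err = np.abs(wrap_phase(ph.phase[interior] -
                                (truth.phase[interior] - np.pi / 2)))
        assert err.max() < 0.05

    def test_zero_signal_raises(self, t0):
        with pytest.raises(ValueError):
            hilbert_phase(np.zeros(1000), t0)


class TestExtractCycle:
    def setup_method(self):
        self.cycle = CycleSpec("hr", 7.0, *band_edges(7.0, 0.3))

    def test_passband_sinusoid_keeps_peak_times(self):
        hr = sinusoid_hr(56, 7.0)
        out = extract_cycle(hr, self.cycle)
        # the input peaks exactly at t = 21 d; the filtered peak nearby must
        # not shift by more than one sample (zero-phase contract)
        centre = 21 * 288
        window = slice(centre - 144, centre + 145)
        peak_out = centre - 144 + int(np.argmax(out[window]))
        assert abs(peak_out - centre) <= 1

    def test_stopband_attenuation(self):
        in_band = extract_cycle(sinusoid_hr(112, 7.0), self.cycle)
        off_band = extract_cycle(sinusoid_hr(112, 28.0), self.cycle)
        mid = slice(28 * 288, -28 * 288)
        assert np.abs(off_band[mid]).max() < 0.1 * np.abs(in_band[mid]).max()

    def test_constant_input_rejected(self):
        out = extract_cycle(make_hr(np.full(56 * 288, 70.0)), self.cycle)
        assert np.abs(out).max() < 1e-6

    def test_band_outside_nyquist_raises(self):
        bad = CycleSpec("hr", 1 / 400.0, band_low=1 / 500.0, band_high=1 / 300.0)
        hr = sinusoid_hr(10, 7.0)
        with pytest.raises(ValueError):
            extract_cycle(hr, bad)


class TestDetectHrCycles:
    def test_pure_sinusoid_recovered(self):
        cfg = cf.ScenarioConfig(duration_days=60, cycle_periods=(7.0,),
                                cycle_amplitudes=(5.0,), noise_sd=0.5,
                                ar1_coeff=0.0, missing_fraction=0.0, seed=3)
        cycles = detect_hr_cycles(fill_missing(cf.generate_hr(cfg)))
        assert any(abs(c.period - 7.0) <= 0.5 for c in cycles)

    def test_constant_series_has_no_cycles(self):
        assert detect_hr_cycles(make_hr(np.full(30 * 288, 70.0))) == []

    def test_too_short_record_is_empty_not_error(self):
        assert detect_hr_cycles(make_hr(70 + np.random.default_rng(0).normal(
            0, 1, 24))) == []

    def test_periods_capped_at_half_record(self):
        cfg = cf.ScenarioConfig(duration_days=20, cycle_periods=(14.0,),
                                cycle_amplitudes=(6.0,), noise_sd=1.0,
                                ar1_coeff=0.0, missing_fraction=0.0, seed=1)
        cycles = detect_hr_cycles(fill_missing(cf.generate_hr(cfg)))
        assert all(c.period <= 10.0 for c in cycles)

    def test_white_noise_false_detections_are_rare(self):
        """At 95% confidence a pure-noise record should average only a
        handful of spurious peaks across the scale axis."""
        counts = []
        for seed in range(10):
            vals = 70 + np.random.default_rng(seed).normal(0, 5, 60 * 288)
            counts.append(len(detect_hr_cycles(make_hr(vals))))
        assert np.mean(counts) <= 3.0

    def test_band_edges_attached(self):
        cycles = detect_hr_cycles(sinusoid_hr(60, 7.0, amplitude=5.0))
        c = min(cycles, key=lambda c: abs(c.period - 7))
        assert c.band_low == pytest.approx(0.7 * c.period)
        assert c.band_high == pytest.approx(1.3 * c.period)


class TestDetectEventCycles:
    def test_exactly_periodic_events(self, t0):
        times = t0 + np.arange(20) * np.timedelta64(7, "D")
        cycles = detect_event_cycles(EventDiary(times), 140.0,
                                     reference_time=t0)
        best = {c.period: c.si for c in cycles}
        assert 7.0 in best and best[7.0] == pytest.approx(1.0)

    def test_uniform_events_rarely_pass_threshold(self, t0):
        total = 0
        for seed in range(5):
            rng = np.random.default_rng(seed)
            times = t0 + (rng.random(200) * 400 * 86_400e9).astype(
                "int64").astype("timedelta64[ns]")
            total += len(detect_event_cycles(EventDiary(times), 400.0,
                                             reference_time=t0))
        assert total <= 2

    def test_planted_locking_recovered(self, t0):
        ok = 0
        for seed in range(5):
            cfg = cf.ScenarioConfig(duration_days=120, event_rate=0.25,
                                    locking_periods=(14.0,), kappa=8.0,
                                    seed=seed)
            hr = cf.generate_hr(cfg)
            d = cf.generate_events(cfg, hr)
            cycles = detect_event_cycles(d, 120.0, reference_time=hr.start_time)
            ok += any(abs(c.period - 14.0) <= 0.5 for c in cycles)
        assert ok == 5

    def test_results_sorted_by_si(self, t0):
        cfg = cf.ScenarioConfig(duration_days=120, event_rate=0.3,
                                locking_periods=(14.0,), kappa=8.0, seed=2)
        hr = cf.generate_hr(cfg)
        cycles = detect_event_cycles(cf.generate_events(cfg, hr), 120.0,
                                     reference_time=hr.start_time)
        sis = [c.si for c in cycles]
        assert sis == sorted(sis, reverse=True)

    def test_no_events_raises(self):
        with pytest.raises(ValueError):
            detect_event_cycles(EventDiary(np.empty(0, "datetime64[ns]")), 50.0)
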