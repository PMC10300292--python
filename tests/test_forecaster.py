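"""Training orchestration, issuance schedule and pseudo-prospective walk."""
import warnings

import numpy as np
import pytest

import cycleforecast as cf
from cycleforecast.containers import DAY, HOUR, EventDiary
from cycleforecast.forecaster import (PseudoProspectiveSeries, daily_average,
                                      initial_training_cutoff, issue_forecast,
                                      run_pseudo_prospective, select_best,
                                      train)
from conftest import T0


def scenario(duration=150, rate=0.25, kappa=8.0, seed=0, **kw):
    cfg = cf.ScenarioConfig(duration_days=duration, event_rate=rate,
                            locking_periods=(14.0,), kappa=kappa, seed=seed,
                            **kw)
    hr = cf.generate_hr(cfg)
    return hr, cf.generate_events(cfg, hr)


@pytest.fixture(scope="module")
def planted():
    return scenario()


@pytest.fixture(scope="module")
def diary_run(planted):
    hr, diary = planted
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return run_pseudo_prospective(hr, diary, modality="diary")


class TestInitialTrainingCutoff:
    def test_cutoff_is_midnight_after_tenth_event(self, t0):
        times = t0 + np.arange(12) * np.timedelta64(3, "D") + \
            np.timedelta64(13, "h")
        cutoff = initial_training_cutoff(EventDiary(times))
        # 10th event on day 27 at 13:00 -> cutoff midnight starting day 28
        assert cutoff == t0 + 28 * DAY

    def test_same_day_events_both_in_training(self, t0):
        times = list(t0 + np.arange(9) * np.timedelta64(2, "D"))
        tenth = t0 + np.timedelta64(20, "D") + np.timedelta64(9, "h")
        eleventh = tenth + np.timedelta64(6, "h")  # same calendar day
        diary = EventDiary(np.array(times + [tenth, eleventh]))
        cutoff = initial_training_cutoff(diary)
        assert cutoff == t0 + 21 * DAY
        assert len(diary.until(cutoff)) == 11

    def test_too_few_events_raises(self, t0):
        with pytest.raises(ValueError, match="10"):
            initial_training_cutoff(EventDiary(t0 + np.arange(5) * DAY))


class TestTrain:
    def test_requires_minimum_training_events(self, planted):
        hr, diary = planted
        early = diary.times[3]
        with pytest.raises(ValueError, match="later cutoff"):
            train(hr, diary, early, modalities=("diary",))

    def test_training_set_grows_monotonically(self, planted):
        hr, diary = planted
        c1 = initial_training_cutoff(diary)
        c2 = c1 + 30 * DAY
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            m1 = train(hr, diary, c1, modalities=("diary",))
            m2 = train(hr, diary, c2, modalities=("diary",))
        assert m2.n_training_events >= m1.n_training_events

    def test_thresholds_fitted_per_modality(self, planted):
        hr, diary = planted
        cutoff = initial_training_cutoff(diary) + 60 * DAY
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            models = train(hr, diary, cutoff)
        for modality in ("hr", "diary", "combined"):
            assert models[modality].model.thresholds is not None


@pytest.fixture(scope="module")
def models(planted):
    hr, diary = planted
    cutoff = initial_training_cutoff(diary) + 60 * DAY
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return train(hr, diary, cutoff)


class TestIssueForecast:

    def test_segment_shape_and_range(self, models):
        seg = issue_forecast(models, models.cutoff, 60.0, "diary")
        assert seg.times.size == 60 * 24
        assert np.all((seg.likelihood >= 0) & (seg.likelihood <= 1))
        assert set(np.unique(seg.risk)) <= {"low", "medium", "high"}

    def test_single_cycle_segment_repeats_with_period(self, planted):
        hr, diary = planted
        cutoff = initial_training_cutoff(diary) + 60 * DAY
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            models = train(hr, diary, cutoff, modalities=("diary",))
        mm = models["diary"]
        # keep only the strongest cycle to test pure periodicity
        mm.model.cycles = mm.model.cycles[:1]
        mm.model.bin_likelihoods = mm.model.bin_likelihoods[:1]
        period_hours = int(mm.model.cycles[0].period * 24)
        seg = issue_forecast(models, models.cutoff, 60.0, "diary")
        same = np.isclose(seg.likelihood[:-period_hours],
                          seg.likelihood[period_hours:])
        # identical up to occasional bin-edge rounding jumps
        assert same.mean() > 0.99

    def test_flat_fallback_without_cycles(self, t0):
        # events with no periodic structure and a tiny window: no cycles
        rng = np.random.default_rng(0)
        n = 30 * 288
        hr = cf.HeartRateSeries(t0, 70 + rng.normal(0, 1, n),
                                np.zeros(n, bool))
        diary = EventDiary(t0 + (rng.random(12) * 4 * 86_400e9).astype(
            "int64").astype("timedelta64[ns]"))
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            models = train(hr, diary, t0 + 5 * DAY, modalities=("diary",))
        if len(models["diary"].model.cycles) == 0:
            seg = issue_forecast(models, t0 + 5 * DAY, 10.0, "diary")
            assert seg.flat
            assert np.allclose(seg.likelihood, models["diary"].flat_rate)

    def test_combined_equals_inputs_when_identical(self, models):
        seg_h = issue_forecast(models, models.cutoff, 10.0, "hr")
        seg_d = issue_forecast(models, models.cutoff, 10.0, "diary")
        seg_c = issue_forecast(models, models.cutoff, 10.0, "combined")
        expected = cf.combine_likelihoods(
            np.vstack([seg_h.likelihood, seg_d.likelihood]))
        assert np.allclose(seg_c.likelihood, expected)
        # idempotence of the logit combination: equal inputs pass through
        assert np.allclose(
            cf.combine_likelihoods(np.vstack([seg_d.likelihood,
                                              seg_d.likelihood])),
            np.clip(seg_d.likelihood, 1e-4, 1 - 1e-4), atol=1e-9)

    def test_issue_before_cutoff_rejected(self, models):
        with pytest.raises(ValueError):
            issue_forecast(models, models.cutoff - DAY, 10.0, "diary")


class TestPseudoProspective:
    def test_weekly_reissue_without_events(self, t0):
        rng = np.random.default_rng(1)
        n = 60 * 288
        hr = cf.HeartRateSeries(t0, 70 + rng.normal(0, 1, n),
                                np.zeros(n, bool))
        # 10 events in the first 10 days, none afterwards
        diary = EventDiary(t0 + np.arange(10) * DAY + np.timedelta64(6, "h"))
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            series = run_pseudo_prospective(hr, diary, modality="diary")
        issues = [np.datetime64(e["issue_time"]) for e in series.issue_log]
        gaps = np.diff(issues).astype("timedelta64[h]").astype(int)
        assert np.all(gaps == 7 * 24)

    def test_event_triggers_retraining_at_next_midnight(self, diary_run,
                                                        planted):
        from cycleforecast.containers import midnight_after
        _, diary = planted
        series = diary_run
        issues = sorted(np.datetime64(e["issue_time"])
                        for e in series.issue_log)
        post = diary.times[diary.times >= series.training_cutoff]
        for t in (x for x in post if midnight_after(x) < series.times[-1]):
            # the first issue after the event must come no later than the
            # midnight ending the event's day
            next_issue = min(i for i in issues if i > t)
            assert next_issue <= midnight_after(t)

    def test_hours_take_covering_segment_value(self, diary_run, planted):
        hr, diary = planted
        series = diary_run
        issue = np.datetime64(series.issue_log[3]["issue_time"])
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            models = train(hr, diary, issue, modalities=("diary",))
            seg = issue_forecast(models, issue, 60.0, "diary")
        sel = series.provenance == issue
        idx = ((series.times[sel] - issue) // HOUR).astype("int64")
        assert np.allclose(series.likelihood[sel], seg.likelihood[idx])

    def test_causality_of_provenance(self, diary_run):
        assert np.all(diary_run.provenance <= diary_run.times)

    def test_training_events_excluded_from_evaluation_span(self, diary_run,
                                                           planted):
        _, diary = planted
        n_train = len(diary.until(diary_run.training_cutoff))
        assert n_train >= 10
        assert diary_run.times[0] >= diary_run.training_cutoff

    def test_rerun_bit_identical(self, planted, diary_run):
        hr, diary = planted
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            again = run_pseudo_prospective(hr, diary, modality="diary")
        assert np.array_equal(again.likelihood, diary_run.likelihood)
        assert np.array_equal(again.risk, diary_run.risk)


class TestDailyAverage:
    @staticmethod
    def make_series(likelihood, start=T0):
        n = len(likelihood)
        times = start + np.arange(n) * HOUR
        return PseudoProspectiveSeries(
            times=times, likelihood=np.asarray(likelihood, float),
            risk=np.full(n, "low", dtype=object), provenance=times,
            modality="diary", training_cutoff=start)

    def test_constant_series(self):
        days, daily = daily_average(self.make_series(np.full(48, 0.4)))
        assert days.size == 2 and np.allclose(daily, 0.4)

    def test_half_zero_half_one_day(self):
        daily = daily_average(self.make_series([0.0] * 12 + [1.0] * 12))[1]
        assert daily[0] == pytest.approx(0.5)

    def test_hand_mean(self):
        rng = np.random.default_rng(4)
        vals = rng.uniform(0, 1, 24)
        daily = daily_average(self.make_series(vals))[1]
        assert daily[0] == pytest.approx(vals.mean())

    def test_partial_days_excluded_with_warning(self):
        series = self.make_series(np.full(30, 0.2),
                                  start=T0 + np.timedelta64(20, "h"))
        with pytest.warns(UserWarning, match="partial"):
            days, daily = daily_average(series)
        assert days.size == 1

    def test_mean_preserved_on_whole_days(self):
        rng = np.random.default_rng(5)
        vals = rng.uniform(0, 1, 96)
        days, daily = daily_average(self.make_series(vals))
        assert daily.mean() == pytest.approx(vals.mean())


class TestSelectBest:
    @staticmethod
    def series_with_auc(likelihood):
        n = len(likelihood)
        times = T0 + np.arange(n) * HOUR
        return PseudoProspectiveSeries(
            times=times, likelihood=np.asarray(likelihood, float),
            risk=np.full(n, "low", dtype=object), provenance=times,
            modality="x", training_cutoff=T0)

    def test_dominant_modality_selected(self):
        ev_times = T0 + np.array([5, 50]) * HOUR
        events = EventDiary(ev_times)
        good = np.zeros(100)
        good[[5, 50]] = 1.0
        flat = np.full(100, 0.3)
        chosen = select_best({"diary": self.series_with_auc(flat),
                              "hr": self.series_with_auc(good),
                              "combined": self.series_with_auc(flat)}, events)
        assert chosen == "hr"

    def test_exact_tie_prefers_diary(self):
        ev_times = T0 + np.array([5, 50]) * HOUR
        events = EventDiary(ev_times)
        same = np.zeros(100)
        same[[5, 50]] = 1.0
        chosen = select_best({"combined": self.series_with_auc(same),
                              "diary": self.series_with_auc(same)}, events)
        assert chosen == "diary"

    def test_no_events_raises(self):
        events = EventDiary(np.empty(0, "datetime64[ns]"))
        with pytest.raises(ValueError):
            select_best({"diary": self.series_with_auc(np.zeros(10))}, events)
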