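"""Mini-heatwave detector, outdoor heatwave rule and event summaries."""

import dataclasses

import numpy as np
import pandas as pd
import pytest

from miniheat import (
    DetectorConfig,
    detect_mini_heatwaves,
    detect_outdoor_heatwaves,
    event_summaries,
    heatwave_mask,
    sensitivity_analysis,
    stratified_event_counts,
)
from miniheat.detector import HeatEvent, events_to_frame
from miniheat.io_timeseries import OutdoorSeries
from tests.conftest import (
    bruteforce_detect,
    events_in_minutes,
    make_indoor,
    random_walk_case,
)

CFG = DetectorConfig()
T0 = "2023-08-02"


def detect_minutes(times, temps, cfg=CFG):
    events = detect_mini_heatwaves(make_indoor(times, temps, t0=T0), cfg)
    return events_in_minutes(events, T0)


class TestDetectMiniHeatwaves:
    def test_never_exceeding_threshold_yields_nothing(self):
        assert detect_minutes(range(120), [20.0] * 120) == []

    def test_single_plateau(self):
        # gentle ramps (|slope| < 2 C/min) so only the plateau is the event
        rise = [21.75, 23.5, 25.25]
        temps = [20.0] * 10 + rise + [27.0] * 15 + rise[::-1] + [20.0] * 10
        events = detect_minutes(range(len(temps)), temps)
        assert events == [(13.0, 28.0)]  # 15-min duration

    def test_short_plateau_discarded(self):
        rise = [21.75, 23.5, 25.25]
        temps = [20.0] * 10 + rise + [27.0] * 8 + rise[::-1] + [20.0] * 10
        assert detect_minutes(range(len(temps)), temps) == []

    def test_nearby_runs_merge(self):
        temps = [20.0] * 10 + [27.0] * 10 + [25.5] * 5 + [27.0] * 10 + [20.0] * 10
        events = detect_minutes(range(45), temps)
        assert len(events) == 1
        (start, end), = events
        assert end - start == 25.0  # merged 25-min event spanning the dip

    def test_rapid_onset_included_below_threshold(self):
        # climbs 2.5 C/min from 20: those points join the event front
        temps = [20.0, 22.5, 25.0, 27.5] + [27.0] * 15 + [20.0] * 10
        events = detect_minutes(range(29), temps)
        assert events[0][0] == 0.0  # onset captured from the first fast point

    def test_steep_drop_excluded(self):
        # above threshold but plunging at -3 C/min: excluded by slope rule
        temps = [27.0] * 15 + [26.5, 23.5, 20.5] + [20.0] * 30
        events = detect_minutes(range(48), temps)
        (start, end), = events
        assert end <= 16.0  # the plunging samples do not extend the event

    def test_long_data_gap_splits_events(self):
        times = list(range(15)) + [t + 100 for t in range(15)]
        temps = [27.0] * 30
        events = detect_minutes(times, temps)
        assert len(events) == 2

    def test_constant_at_threshold_counts(self):
        events = detect_minutes(range(15), [26.0] * 15)
        assert events == [(0.0, 15.0)]

    def test_empty_series_raises(self):
        with pytest.raises(ValueError):
            detect_mini_heatwaves(make_indoor([], []))

    def test_events_disjoint_sorted_and_long_enough(self, rng):
        for _ in range(25):
            times, temps = random_walk_case(rng, max_len=800)
            events = detect_mini_heatwaves(make_indoor(times, temps), CFG)
            for ev in events:
                assert ev.duration_min >= CFG.min_duration
                assert ev.start < ev.end
                assert ev.peak_temp >= ev.mean_temp
            for a, b in zip(events, events[1:]):
                assert a.end <= b.start

    def test_matches_bruteforce_oracle_on_random_walks(self, rng):
        for _ in range(60):
            times, temps = random_walk_case(rng, max_len=600)
            got = detect_minutes(times, temps)
            want = bruteforce_detect(list(times), list(temps), CFG)
            assert got == pytest.approx(want)

    def test_monotone_in_min_duration(self, rng):
        times, temps = random_walk_case(rng, max_len=1500)
        series = make_indoor(times, temps)
        prev_n = None
        prev_median = None
        for md in (10, 30, 60, 120):
            cfg = dataclasses.replace(CFG, min_duration=float(md))
            events = detect_mini_heatwaves(series, cfg)
            if prev_n is not None:
                assert len(events) <= prev_n
            if events:
                med = float(np.median([e.duration_min for e in events]))
                if prev_median is not None:
                    assert med >= prev_median - 1e-9
                prev_median = med
            prev_n = len(events)

    def test_monotone_in_temp_threshold(self, rng):
        times, temps = random_walk_case(rng, max_len=1500)
        series = make_indoor(times, temps)
        prev_minutes = None
        for th in (24.0, 26.0, 28.0, 30.0):
            cfg = dataclasses.replace(CFG, temp_threshold=th)
            total = sum(e.duration_min for e in detect_mini_heatwaves(series, cfg))
            if prev_minutes is not None:
                assert total <= prev_minutes + 1e-9
            prev_minutes = total

    def test_config_validation(self):
        with pytest.raises(ValueError):
            DetectorConfig(min_duration=0)
        with pytest.raises(ValueError):
            DetectorConfig(slope_in=-1)
        with pytest.raises(ValueError):
            DetectorConfig(slope_out=1)


def outdoor_daily(maxima, start="2023-08-02"):
    """One sample per day at 14:00, value = that day's maximum."""
    idx = pd.DatetimeIndex(
        [pd.Timestamp(start) + pd.Timedelta(days=i, hours=14)
         for i in range(len(maxima))])
    return OutdoorSeries(pd.DataFrame(
        {"temperature": maxima, "relative_humidity": [50.0] * len(maxima)},
        index=idx))


class TestOutdoorHeatwaves:
    def test_three_hot_days(self):
        waves = detect_outdoor_heatwaves(outdoor_daily([29, 29, 29]))
        assert len(waves) == 1
        assert waves[0].n_days == 3

    def test_broken_run(self):
        waves = detect_outdoor_heatwaves(outdoor_daily([29, 27, 29, 29, 29]))
        assert len(waves) == 1
        assert waves[0].start_date == pd.Timestamp("2023-08-04").date()
        assert waves[0].end_date == pd.Timestamp("2023-08-06").date()

    def test_too_short(self):
        assert detect_outdoor_heatwaves(outdoor_daily([29, 29])) == []

    def test_degenerate_threshold_spans_series(self):
        waves = detect_outdoor_heatwaves(
            outdoor_daily([20, 21, 22]), threshold=-np.inf, min_days=1)
        assert len(waves) == 1
        assert waves[0].n_days == 3

    def test_missing_day_breaks_consecutiveness(self):
        s = outdoor_daily([29, 29, 29, 29, 29, 29])
        # remove day 3 entirely
        data = s.data.drop(s.data.index[2])
        waves = detect_outdoor_heatwaves(OutdoorSeries(data))
        assert [w.n_days for w in waves] == [3]  # only the trailing run of 3

    def test_threshold_is_inclusive(self):
        waves = detect_outdoor_heatwaves(outdoor_daily([28.0, 28.0, 28.0]))
        assert len(waves) == 1


class TestHeatwaveMask:
    def test_inside_and_outside(self):
        waves = detect_outdoor_heatwaves(outdoor_daily([29, 29, 29]))
        ts = pd.DatetimeIndex([
            "2023-08-02 00:00",  # midnight of first day -> inside
            "2023-08-04 23:59",
            "2023-08-05 00:00",  # day after -> outside
            "2023-07-30 12:00",
        ])
        assert heatwave_mask(waves, ts).tolist() == [True, True, False, False]

    def test_no_events_all_false(self):
        ts = pd.date_range("2023-08-02", periods=5, freq="1D")
        assert not heatwave_mask([], ts).any()


class TestEventSummaries:
    def test_empty(self):
        s = event_summaries([])
        assert s.n_affected == 0
        assert s.mean_count is None
        assert s.start_hour_hist.sum() == 0

    def test_single_event_hour_bins(self):
        ev = HeatEvent("A", pd.Timestamp("2023-08-02 15:00"),
                       pd.Timestamp("2023-08-02 20:00"), 300.0, 27.0, 26.5)
        s = event_summaries([ev])
        assert s.start_hour_hist[15] == 1
        assert s.stop_hour_hist[20] == 1
        assert s.median_duration == 300.0

    def test_histogram_conservation(self, rng):
        events = []
        for i in range(40):
            start = pd.Timestamp("2023-08-02") + pd.Timedelta(
                minutes=int(rng.integers(0, 40000)))
            dur = int(rng.integers(10, 600))
            events.append(HeatEvent(f"S{i%7}", start,
                                    start + pd.Timedelta(minutes=dur),
                                    float(dur), 27.0, 26.5))
        s = event_summaries(events)
        assert s.start_hour_hist.sum() == 40
        assert s.stop_hour_hist.sum() == 40
        assert sum(s.counts_per_household.values()) == 40


def mk_event(sid, start_min=0, dur=60):
    start = pd.Timestamp("2023-08-02") + pd.Timedelta(minutes=start_min)
    return HeatEvent(sid, start, start + pd.Timedelta(minutes=dur),
                     float(dur), 27.0, 26.5)


class TestStratifiedCounts:
    households = pd.DataFrame(
        {"epc": ["B", "B", "C"], "imd": [1, 2, 2],
         "condition": ["new and/or in good condition"] * 3},
        index=pd.Index(["A", "B", "C"], name="sensor_id"))

    def test_group_mean(self):
        events = [mk_event("A")] * 4 + [mk_event("B")] * 6
        out = stratified_event_counts(events, self.households, "epc")
        assert out["B"] == 5.0
        assert "C" not in out.index  # stratum without affected households

    def test_all_households_mode(self):
        events = [mk_event("A")] * 4
        out = stratified_event_counts(events, self.households, "epc",
                                      affected_only=False)
        assert out["B"] == 2.0  # (4 + 0) / 2
        assert out["C"] == 0.0

    def test_unknown_sensor_raises(self):
        with pytest.raises(KeyError):
            stratified_event_counts([mk_event("Z")], self.households, "epc")

    def test_unknown_stratum_raises(self):
        with pytest.raises(KeyError):
            stratified_event_counts([], self.households, "floor_area")

    def test_matches_groupby_oracle(self, rng):
        sids = [f"S{i}" for i in range(12)]
        hh = pd.DataFrame(
            {"epc": rng.choice(["B", "C", "D", "E"], size=12)},
            index=pd.Index(sids, name="sensor_id"))
        events = [mk_event(rng.choice(sids)) for _ in range(50)]
        out = stratified_event_counts(events, hh, "epc")
        counts = {}
        for ev in events:
            counts[ev.sensor_id] = counts.get(ev.sensor_id, 0) + 1
        by_level = {}
        for sid, c in counts.items():
            by_level.setdefault(hh.loc[sid, "epc"], []).append(c)
        for level, vals in by_level.items():
            assert out[level] == pytest.approx(np.mean(vals))


class TestSensitivityAnalysis:
    def test_duration_cutoffs_on_single_event(self):
        temps = [20.0] * 10 + [27.0] * 50 + [20.0] * 10
        series = make_indoor(range(70), temps)
        table = sensitivity_analysis([series], CFG, [10, 30, 60])
        assert table["households_affected"].tolist() == [1, 1, 0]

    def test_degenerate_single_threshold_equals_direct_detection(self):
        temps = [20.0] * 10 + [27.0] * 50 + [20.0] * 10
        series = make_indoor(range(70), temps)
        table = sensitivity_analysis([series], CFG, [10])
        events = detect_mini_heatwaves(series, CFG)
        assert table.loc[0, "households_affected"] == 1
        assert table.loc[0, "median_event_duration_min"] == pytest.approx(
            float(np.median([e.duration_min for e in events])))

    def test_rows_match_per_threshold_recomputation(self, rng):
        series = [make_indoor(*random_walk_case(rng, max_len=600),
                              sensor_id=f"S{i}") for i in range(6)]
        table = sensitivity_analysis(series, CFG, [10, 30, 60])
        for _, row in table.iterrows():
            cfg = dataclasses.replace(
                CFG, min_duration=float(row["duration_threshold_min"]))
            events = [e for s in series for e in detect_mini_heatwaves(s, cfg)]
            summ = event_summaries(events)
            assert row["households_affected"] == summ.n_affected
            if summ.n_affected:
                assert row["mean_count_per_household"] == pytest.approx(
                    summ.mean_count)
                assert row["median_event_duration_min"] == pytest.approx(
                    summ.median_duration)

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            sensitivity_analysis([], CFG, [10])


def test_events_frame_schema():
    frame = events_to_frame([mk_event("A")])
    assert list(frame.columns) == [
        "sensor_id", "start", "end", "duration_min", "peak_temp", "mean_temp"]
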