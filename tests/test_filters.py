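"""Rule-based filter branches: reflection removal, gap segmentation,
criterion evaluation, and cross-checks against an independent
brute-force validator."""

import dataclasses

import numpy as np
import pytest

from pulsetrain import (
    ClickTrainCriteria,
    PulseSeries,
    VesselCriteria,
    detect_click_trains,
    detect_vessel_events,
    evaluate_clicktrain_criteria,
    passed_events,
    remove_reflections,
    segment_by_gap,
)
from pulsetrain.filters import events_to_frame
from pulsetrain.simulate import ClickTrainSpec, simulate_click_train

from _oracle import brute_click_candidates, brute_vessel_candidates
from conftest import constant_train, random_pulse_tuples, series_from_tuples


def series_at(times, spl_a=20.0, splr=1.0, td=0.0):
    t = np.asarray(times, dtype=float)
    a = np.full(len(t), spl_a)
    return PulseSeries(t, a, a / splr, np.full(len(t), td))


class TestRemoveReflections:
    def test_reflection_within_2ms_dropped(self):
        # 1.0 ms after the kept pulse at 0 is a reflection; 2.5 ms is not
        out = remove_reflections(series_at([0.0, 1.0, 2.5]), 2.0)
        np.testing.assert_array_equal(out.t_ms, [0.0, 2.5])

    def test_exact_2ms_interval_kept(self):
        out = remove_reflections(series_at([0.0, 2.0, 4.0]), 2.0)
        assert len(out) == 3

    def test_single_pulse_unchanged(self):
        out = remove_reflections(series_at([7.5]), 2.0)
        np.testing.assert_array_equal(out.t_ms, [7.5])

    def test_sweep_measures_from_last_kept_pulse(self):
        # 1.5 and 3.0 are both within 2 ms of the last KEPT pulse
        out = remove_reflections(series_at([0.0, 1.5, 3.0, 4.5]), 2.0)
        np.testing.assert_array_equal(out.t_ms, [0.0, 3.0])

    def test_idempotent(self, rng):
        for _ in range(50):
            series = series_from_tuples(random_pulse_tuples(rng))
            once = remove_reflections(series, 2.0)
            twice = remove_reflections(once, 2.0)
            np.testing.assert_array_equal(once.t_ms, twice.t_ms)


class TestSegmentByGap:
    def test_click_rule_splits_on_150ms_gap(self):
        series = series_at([0.0, 50.0, 100.0, 250.0, 300.0])
        segments = segment_by_gap(series, 100.0, "exceeds")
        assert segments == [(0, 3), (3, 5)]

    def test_interval_exactly_100ms_stays_inside(self):
        series = series_at([0.0, 100.0, 200.0, 300.0])
        assert segment_by_gap(series, 100.0, "exceeds") == [(0, 4)]

    def test_interval_exactly_500ms_splits_vessel(self):
        series = series_at([0.0, 500.0, 1000.0])
        segments = segment_by_gap(series, 500.0, "at_or_exceeds")
        assert segments == [(0, 1), (1, 2), (2, 3)]

    def test_partition_property(self, rng):
        for _ in range(100):
            series = series_from_tuples(random_pulse_tuples(rng))
            segments = segment_by_gap(series, 100.0, "exceeds")
            covered = [i for start, stop in segments for i in range(start, stop)]
            assert covered == list(range(len(series)))


class TestClickTrainCriteria:
    def test_clean_constant_train_passes_all_nine(self):
        flags = evaluate_clicktrain_criteria(constant_train(10, 10.0))
        assert all(flags.values()) and len(flags) == 9

    def test_five_pulses_fail_only_count(self):
        flags = evaluate_clicktrain_criteria(constant_train(5, 10.0))
        assert not flags["min_pulses"]
        assert all(v for k, v in flags.items() if k != "min_pulses")

    def test_low_splr_fails_ratio_criterion(self):
        flags = evaluate_clicktrain_criteria(constant_train(10, 10.0, splr=0.5))
        assert not flags["splr"]
        assert all(v for k, v in flags.items() if k != "splr")

    def test_splr_all_pulses_mode(self):
        series = constant_train(10, 10.0)
        series.spl_b[0] = series.spl_a[0] / 0.5  # one pulse at ratio 0.5
        mean_mode = evaluate_clicktrain_criteria(series)
        strict = evaluate_clicktrain_criteria(
            series, ClickTrainCriteria(splr_mode="all_pulses")
        )
        assert mean_mode["splr"] and not strict["splr"]

    def test_short_duration_fails(self):
        # 6 pulses at 2 ms spacing: 10 ms duration < 12 ms
        flags = evaluate_clicktrain_criteria(constant_train(6, 2.0))
        assert not flags["duration"]

    def test_spread_td_fails(self):
        series = constant_train(10, 10.0)
        series.td_us = np.where(np.arange(10) % 2 == 0, 50.0, -50.0)
        assert not evaluate_clicktrain_criteria(series)["sd_td"]

    def test_irregular_intervals_fail_cv(self):
        series = series_at([0.0, 5.0, 100.0, 102.0, 190.0, 192.5, 280.0])
        assert not evaluate_clicktrain_criteria(series)["cv_pulse_interval"]


class TestDetectClickTrains:
    def test_empty_series(self):
        empty = np.empty(0)
        assert detect_click_trains(PulseSeries(empty, empty, empty, empty)) == []

    def test_clean_simulated_train_detected(self, rng):
        series, ann = simulate_click_train(ClickTrainSpec(), rng)
        events = passed_events(detect_click_trains(series))
        assert len(events) == 1
        assert events[0].t_start_ms == ann.t_start_ms
        assert events[0].t_end_ms == ann.t_end_ms

    def test_two_trains_across_silence(self, rng):
        s1, _ = simulate_click_train(ClickTrainSpec(), rng, t0_ms=0.0)
        s2, _ = simulate_click_train(ClickTrainSpec(), rng, t0_ms=s1.t_ms[-1] + 5000.0)
        merged = PulseSeries(
            np.concatenate([s1.t_ms, s2.t_ms]),
            np.concatenate([s1.spl_a, s2.spl_a]),
            np.concatenate([s1.spl_b, s2.spl_b]),
            np.concatenate([s1.td_us, s2.td_us]),
        )
        assert len(passed_events(detect_click_trains(merged))) == 2

    def test_events_disjoint_in_time(self, rng):
        for _ in range(20):
            series = series_from_tuples(random_pulse_tuples(rng))
            events = detect_click_trains(series)
            for a, b in zip(events, events[1:]):
                assert a.t_end_ms < b.t_start_ms


class TestDetectVesselEvents:
    def test_81_pulses_over_8s_rejected_on_duration(self):
        series = series_at(np.arange(81) * 100.0)
        events = detect_vessel_events(series)
        assert len(events) == 1
        assert events[0].criterion_flags["min_pulses"]
        assert not events[0].criterion_flags["duration"]

    def test_80_pulses_rejected_on_count(self):
        series = series_at(np.arange(80) * 200.0)  # spans 15.8 s
        events = detect_vessel_events(series)
        assert events[0].criterion_flags["duration"]
        assert not events[0].criterion_flags["min_pulses"]

    def test_dense_long_event_accepted(self, rng):
        gaps = np.round(rng.uniform(50.0, 400.0, 119) * 2) / 2
        series = series_at(np.concatenate(([0.0], np.cumsum(gaps))))
        assert series.t_ms[-1] >= 10_000.0
        assert len(passed_events(detect_vessel_events(series))) == 1


class TestOracleEquivalence:
    def test_click_branch_flags_agree(self, rng):
        for _ in range(300):
            pulses = random_pulse_tuples(rng)
            mine = detect_click_trains(series_from_tuples(pulses))
            ref = brute_click_candidates(pulses)
            assert [(e.t_start_ms, e.t_end_ms, e.criterion_flags) for e in mine] == ref

    def test_vessel_branch_flags_agree(self, rng):
        for _ in range(300):
            pulses = random_pulse_tuples(rng)
            mine = detect_vessel_events(series_from_tuples(pulses))
            ref = brute_vessel_candidates(pulses)
            assert [(e.t_start_ms, e.t_end_ms, e.criterion_flags) for e in mine] == ref


class TestMonotonicity:
    @pytest.mark.parametrize(
        "field, tighter",
        [
            ("min_pulses", 8),
            ("max_cv_pi", 0.2),
            ("min_splr", 0.8),
            ("min_duration_ms", 50.0),
            ("max_sd_td_us", 10.0),
            ("max_median_pi_ms", 50.0),
        ],
    )
    def test_tightening_never_adds_candidates(self, rng, field, tighter):
        base = ClickTrainCriteria()
        tight = dataclasses.replace(base, **{field: tighter})
        for _ in range(50):
            series = series_from_tuples(random_pulse_tuples(rng))
            n_base = len(passed_events(detect_click_trains(series, base)))
            n_tight = len(passed_events(detect_click_trains(series, tight)))
            assert n_tight <= n_base


def test_events_export_columns(rng):
    series = series_from_tuples(random_pulse_tuples(rng, n_max=30))
    frame = events_to_frame(detect_click_trains(series))
    assert list(frame.columns[:5]) == [
        "kind", "t_start_ms", "t_end_ms", "n_pulses", "passed",
    ]
    assert frame.shape[1] == 5 + 9


def test_invalid_criteria_rejected():
    with pytest.raises(ValueError):
        ClickTrainCriteria(min_pi_ms=-1.0)
    with pytest.raises(ValueError):
        ClickTrainCriteria(min_pi_ms=200.0)  # >= max_pi_ms
    with pytest.raises(ValueError):
        VesselCriteria(min_pulses=0)
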