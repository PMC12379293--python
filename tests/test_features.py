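"""Per-event feature vectors: buzz detection, statistics, timestamps."""

from datetime import datetime, timezone

import numpy as np
import pytest

from pulsetrain import (
    CLICK_FEATURE_COLUMNS,
    VESSEL_FEATURE_COLUMNS,
    PulseSeries,
    compute_buzz_check,
    detect_click_trains,
    extract_features,
    features_frame,
    passed_events,
)
from pulsetrain.simulate import (
    ClickTrainSpec,
    DEFAULT_BUZZ_SPEC,
    simulate_click_train,
)

from conftest import constant_train


def spanning_event(series, kind="clicktrain"):
    from pulsetrain.filters import CandidateEvent

    return CandidateEvent(
        kind=kind,
        start_index=0,
        stop_index=len(series),
        t_start_ms=float(series.t_ms[0]),
        t_end_ms=float(series.t_ms[-1]),
        criterion_flags={},
    )


UTC0 = datetime(2023, 1, 1, 0, 0, tzinfo=timezone.utc)


class TestBuzzCheck:
    @pytest.mark.parametrize(
        "intervals, expected",
        [
            ([8.0] * 4, 1),  # 5 pulses at 8 ms spacing
            ([50.0] * 5, 0),  # 6 pulses, no interval <= 10 ms
            ([8.0, 8.0, 40.0, 8.0, 8.0, 8.0, 8.0], 1),  # final run of 5 pulses
            ([8.0, 8.0, 40.0, 8.0, 8.0, 40.0, 8.0], 0),  # runs of only 3 pulses
            ([10.0] * 4, 1),  # boundary: exactly 10 ms qualifies
            ([10.5] * 4, 0),
        ],
    )
    def test_run_detection(self, intervals, expected):
        times = np.concatenate(([0.0], np.cumsum(intervals)))
        assert compute_buzz_check(times) == expected

    def test_brute_force_agreement(self, rng):
        # oracle: enumerate every window of 5 consecutive pulses
        for _ in range(200):
            n = int(rng.integers(2, 20))
            gaps = rng.choice([2.5, 8.0, 10.0, 12.0, 60.0], size=n - 1)
            times = np.concatenate(([0.0], np.cumsum(gaps)))
            expected = int(
                any(
                    all(times[j + 1] - times[j] <= 10.0 for j in range(i, i + 4))
                    for i in range(n - 4)
                )
            )
            assert compute_buzz_check(times) == expected

    def test_monotone_under_dense_extension(self, rng):
        # appending pulses at <= 10 ms spacing never flips 1 -> 0
        times = list(np.concatenate(([0.0], np.cumsum([8.0] * 4))))
        assert compute_buzz_check(times) == 1
        for _ in range(20):
            times.append(times[-1] + rng.choice([2.5, 5.0, 10.0]))
            assert compute_buzz_check(times) == 1


class TestExtractFeatures:
    def test_constant_train_degeneracy(self):
        series = constant_train(6, 10.0)
        series.start_datetime = UTC0
        f = extract_features(series, spanning_event(series), "click")
        assert f["sd_pi_ms"] == 0.0
        assert f["max_pi_ms"] == f["min_pi_ms"] == f["av_pi_ms"] == 10.0
        assert f["duration_ms"] == 50.0
        assert f["np_pulses"] == 6

    def test_splr_statistics_hand_computed(self):
        spl_a = np.array([20.0, 20.0, 20.0])
        spl_b = spl_a / np.array([1.0, 0.8, 0.6])
        series = PulseSeries([0.0, 10.0, 20.0], spl_a, spl_b, [0.0] * 3,
                             start_datetime=UTC0)
        f = extract_features(series, spanning_event(series), "click")
        assert f["max_splr"] == pytest.approx(1.0)
        assert f["av_splr"] == pytest.approx(0.8)
        assert f["sd_splr"] == pytest.approx(0.2)  # sample SD of (1.0, 0.8, 0.6)

    def test_epoch_minutes_truncate(self):
        # first pulse 90 s into a recording started 2023-01-01T00:00Z
        series = constant_train(6, 10.0, t0=90_000.0)
        series.start_datetime = UTC0
        f = extract_features(series, spanning_event(series), "click")
        epoch_min_of_start = int(UTC0.timestamp() // 60)
        assert f["start_epoch_min"] == epoch_min_of_start + 1
        assert f["end_epoch_min"] == f["start_epoch_min"]

    def test_signed_td_maximum(self):
        series = constant_train(6, 10.0)
        series.td_us = np.array([-100.0, -90.0, -80.0, -70.0, -60.0, -50.0])
        series.start_datetime = UTC0
        f = extract_features(series, spanning_event(series), "click")
        assert f["max_td_us"] == -50.0  # signed, not absolute

    def test_branch_vector_lengths(self):
        series = constant_train(6, 10.0)
        series.start_datetime = UTC0
        click = extract_features(series, spanning_event(series), "click")
        vessel = extract_features(series, spanning_event(series, "vessel"), "vessel")
        assert tuple(click) == CLICK_FEATURE_COLUMNS and len(click) == 18
        assert tuple(vessel) == VESSEL_FEATURE_COLUMNS and len(vessel) == 17
        assert "buzz_check" not in vessel

    def test_missing_start_datetime_is_config_error(self):
        series = constant_train(6, 10.0)
        with pytest.raises(ValueError, match="start_datetime"):
            extract_features(series, spanning_event(series), "click")

    def test_single_pulse_event_rejected(self):
        series = constant_train(6, 10.0)
        series.start_datetime = UTC0
        event = spanning_event(series)
        one = type(event)(
            kind="clicktrain", start_index=0, stop_index=1,
            t_start_ms=0.0, t_end_ms=0.0, criterion_flags={},
        )
        with pytest.raises(ValueError, match="2 pulses"):
            extract_features(series, one, "click")


class TestInvariants:
    def test_simulated_buzz_has_buzz_check(self, rng):
        series, _ = simulate_click_train(DEFAULT_BUZZ_SPEC, rng)
        assert compute_buzz_check(series.t_ms) == 1

    def test_simulated_regular_train_is_not_buzz(self, rng):
        series, _ = simulate_click_train(ClickTrainSpec(), rng)
        assert compute_buzz_check(series.t_ms) == 0

    def test_passed_candidates_consistent_with_flags(self, rng):
        # for any passed click candidate the feature stats respect the criteria
        for _ in range(20):
            series, _ = simulate_click_train(ClickTrainSpec(), rng)
            series.start_datetime = UTC0
            events = passed_events(detect_click_trains(series))
            frame = features_frame(series, events, "click")
            assert (frame["sd_pi_ms"] / frame["av_pi_ms"] <= 0.4).all()
            assert (frame["av_splr"] >= 0.6).all()
            assert (frame["sd_td_us"] < 25.0).all()
            assert (frame["min_pi_ms"] <= frame["av_pi_ms"]).all()
            assert (frame["av_pi_ms"] <= frame["max_pi_ms"]).all()

    def test_csv_round_trip_preserves_features(self, rng, tmp_path):
        series, _ = simulate_click_train(ClickTrainSpec(), rng)
        series.start_datetime = UTC0
        events = passed_events(detect_click_trains(series))
        frame = features_frame(series, events, "click")
        path = tmp_path / "features.csv"
        frame.to_csv(path, index=False)
        import pandas as pd

        back = pd.read_csv(path)
        for col in CLICK_FEATURE_COLUMNS:
            np.testing.assert_allclose(back[col], frame[col], rtol=1e-9)
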