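"""Alert rules, boundary behaviour, online/offline equivalence, and series I/O."""

import numpy as np
import pytest

import plantarkit as pk
from plantarkit.series import PressureSeries, SeriesFormatError


def _stand(seconds, seed=0):
    return pk.generate_mixed_session([(pk.Posture.STAND, seconds)], seed=seed)


def _stream_events(series, rules=None):
    frames = zip(series.times, series.values)
    return list(pk.monitor_stream(frames, rules, series.sample_rate))


def _as_key_set(events):
    return {
        (e.kind, round(e.onset, 9), round(e.duration, 9), e.channels,
         round(e.peak_value, 9))
        for e in events
    }


class TestRules:
    def test_sustained_35s_gives_one_event(self):
        s = pk.inject_event(_stand(50), "SUSTAINED_200", at=10.0, duration=35.0)
        events = [e for e in pk.scan_alerts(s)
                  if e.kind is pk.AlertKind.HIGH_PRESSURE_SUSTAINED]
        assert len(events) == 1
        assert events[0].duration == pytest.approx(35.0)
        assert events[0].onset == pytest.approx(10.0)
        assert events[0].channels == (6,)

    def test_29s_run_raises_nothing(self):
        s = pk.inject_event(_stand(40), "SUSTAINED_200", at=5.0, duration=29.0)
        assert not [e for e in pk.scan_alerts(s)
                    if e.kind is pk.AlertKind.HIGH_PRESSURE_SUSTAINED]

    def test_exactly_30s_run_raises_nothing(self):
        """The rule reads 'more than 30 s': a run of exactly 30 s is silent."""
        s = pk.inject_event(_stand(40), "SUSTAINED_200", at=5.0, duration=30.0)
        assert not [e for e in pk.scan_alerts(s)
                    if e.kind is pk.AlertKind.HIGH_PRESSURE_SUSTAINED]

    def test_zero_series_has_no_events(self):
        s = PressureSeries(np.zeros((2000, 8)), 200.0)
        assert pk.scan_alerts(s) == []

    def test_spike_single_frame(self):
        s = pk.inject_event(_stand(10), "SPIKE_500", at=4.0)
        spikes = [e for e in pk.scan_alerts(s)
                  if e.kind is pk.AlertKind.HIGH_PRESSURE_SPIKE]
        assert len(spikes) == 1
        assert spikes[0].duration == pytest.approx(1 / 200)
        assert spikes[0].peak_value > 500

    def test_no_spike_below_threshold(self):
        v = np.full((1000, 8), 499.9)
        s = PressureSeries(v, 200.0)
        assert not [e for e in pk.scan_alerts(s)
                    if e.kind is pk.AlertKind.HIGH_PRESSURE_SPIKE]

    def test_uneven_pressure_alert(self):
        s = pk.inject_event(_stand(10), "ASYMMETRY_45", at=2.0, duration=3.0)
        uneven = [e for e in pk.scan_alerts(s)
                  if e.kind is pk.AlertKind.UNEVEN_PRESSURE]
        assert len(uneven) == 1
        assert uneven[0].peak_value > 0.45
        assert uneven[0].duration >= 3.0 - 1e-9

    def test_uneven_below_one_second_is_silent(self):
        s = pk.inject_event(_stand(10), "ASYMMETRY_45", at=2.0, duration=0.5)
        assert not [e for e in pk.scan_alerts(s)
                    if e.kind is pk.AlertKind.UNEVEN_PRESSURE]

    def test_overuse_after_30_minutes(self):
        # 31 min of continuous standing load at 10 Hz to keep the array small
        v = np.full((31 * 60 * 10, 8), 20.0)
        s = PressureSeries(v, 10.0)
        overuse = [e for e in pk.scan_alerts(s)
                   if e.kind is pk.AlertKind.OVERUSE]
        assert len(overuse) == 1
        assert overuse[0].duration == pytest.approx(31 * 60)

    def test_rest_break_resets_overuse(self):
        v = np.full((40 * 60 * 10, 8), 20.0)
        v[15 * 60 * 10 : 15 * 60 * 10 + 50] = 0.0  # 5 s rest
        s = PressureSeries(v, 10.0)
        assert not [e for e in pk.scan_alerts(s)
                    if e.kind is pk.AlertKind.OVERUSE]

    def test_fatigue_window_rule(self):
        s = _stand(10)
        labels = [int(pk.Posture.WALK)] * 5 + [int(pk.Posture.WALK_FATIGUED)] * 4
        events = [e for e in pk.scan_alerts(s, window_labels=np.array(labels))
                  if e.kind is pk.AlertKind.FATIGUE]
        assert len(events) == 1
        assert events[0].onset == pytest.approx(5 * 30 / 200)

    def test_two_fatigued_windows_insufficient(self):
        s = _stand(10)
        labels = [int(pk.Posture.WALK)] * 5 + [int(pk.Posture.RUN_FATIGUED)] * 2
        assert not [e for e in pk.scan_alerts(s, window_labels=np.array(labels))
                    if e.kind is pk.AlertKind.FATIGUE]

    def test_uncalibrated_series_rejected(self):
        s = PressureSeries(np.full((100, 8), 0.5), 200.0, unit="relcap")
        with pytest.raises(ValueError):
            pk.scan_alerts(s)


def _random_fixture(seed):
    """Short random record with occasional injected anomalies."""
    rng = np.random.default_rng(seed)
    s = _stand(8.0, seed=seed)
    if seed % 3 == 0:
        s = pk.inject_event(s, "SPIKE_500", at=float(rng.uniform(0.5, 7.0)))
    if seed % 3 == 1:
        s = pk.inject_event(
            s, "SUSTAINED_200", at=1.0, duration=float(rng.uniform(0.5, 5.0))
        )
    if seed % 3 == 2:
        s = pk.inject_event(
            s, "ASYMMETRY_45", at=2.0, duration=float(rng.uniform(0.5, 4.0))
        )
    return s


class TestOnlineOfflineEquivalence:
    def test_equivalence_over_100_seeded_fixtures(self):
        rules = pk.AlertRuleSet(sustained_duration=2.0, overuse_duration=5.0)
        for seed in range(100):
            s = _random_fixture(seed)
            offline = pk.scan_alerts(s, rules)
            online = _stream_events(s, rules)
            assert _as_key_set(online) == _as_key_set(offline), f"seed {seed}"

    def test_event_count_invariant_to_chunking(self):
        rules = pk.AlertRuleSet(sustained_duration=2.0, overuse_duration=5.0)
        s = _random_fixture(1)
        expected = _as_key_set(pk.scan_alerts(s, rules))
        for chunk in (1, 7, 100):
            monitor = pk.AlertMonitor(rules, s.sample_rate)
            events = []
            for start in range(0, s.n_samples, chunk):
                for i in range(start, min(start + chunk, s.n_samples)):
                    events.extend(monitor.process_frame(s.times[i], s.values[i]))
            events.extend(monitor.finalize())
            assert _as_key_set(events) == expected

    def test_empty_stream_yields_nothing(self):
        assert list(pk.monitor_stream(iter([]))) == []

    def test_single_overloaded_frame_is_one_spike(self):
        events = list(pk.monitor_stream([(0.0, np.full(8, 510.0))]))
        kinds = [e.kind for e in events]
        assert kinds.count(pk.AlertKind.HIGH_PRESSURE_SPIKE) == 1

    def test_out_of_order_timestamp_rejected(self):
        monitor = pk.AlertMonitor()
        monitor.process_frame(0.0, np.zeros(8))
        with pytest.raises(ValueError):
            monitor.process_frame(0.0, np.zeros(8))


class TestSeriesIO:
    def test_round_trip_preserves_values(self, tmp_path, rng):
        s = PressureSeries(
            rng.uniform(0, 400, size=(500, 8)), 200.0,
            rng.integers(0, 7, size=500),
        )
        path = tmp_path / "series.csv"
        pk.write_series(s, path)
        back = pk.read_series(path)
        np.testing.assert_allclose(back.values, s.values, rtol=1e-9)
        np.testing.assert_array_equal(back.annotation, s.annotation)
        assert back.sample_rate == pytest.approx(200.0)

    def test_relcap_unit_flag_round_trip(self, tmp_path):
        s = PressureSeries(np.full((100, 8), 0.5), 200.0, unit="relcap")
        path = tmp_path / "raw.csv"
        pk.write_series(s, path)
        assert pk.read_series(path).unit == "relcap"

    def test_malformed_row_names_line(self, tmp_path):
        path = tmp_path / "bad.csv"
        path.write_text(
            "time_s,S1,S2,S3,S4,S5,S6,S7,S8\n"
            "0.000,1,2,3,4,5,6,7,8\n"
            "0.005,1,2,3,4,5,6,7,-9\n",
            encoding="utf-8",
        )
        with pytest.raises(SeriesFormatError, match="line 3"):
            pk.read_series(path)

    def test_non_monotone_time_names_line(self, tmp_path):
        path = tmp_path / "bad.csv"
        path.write_text(
            "time_s,S1,S2,S3,S4,S5,S6,S7,S8\n"
            "0.000,1,2,3,4,5,6,7,8\n"
            "0.000,1,2,3,4,5,6,7,8\n",
            encoding="utf-8",
        )
        with pytest.raises(SeriesFormatError, match="line 3"):
            pk.read_series(path)

    def test_wrong_column_count_rejected(self, tmp_path):
        path = tmp_path / "bad.csv"
        path.write_text("time_s,S1,S2\n0,1,2\n", encoding="utf-8")
        with pytest.raises(SeriesFormatError):
            pk.read_series(path)

    def test_empty_file_rejected(self, tmp_path):
        path = tmp_path / "empty.csv"
        path.write_text("", encoding="utf-8")
        with pytest.raises(SeriesFormatError):
            pk.read_series(path)
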