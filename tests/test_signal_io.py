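"""Recording I/O, canonical resampling, windowing and annotation labelling."""
import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import tremorkit as tk
from tremorkit.signal_io import (AnnotationTrack, FormatError, GyroRecording,
                                 Segment, coverage_check, label_windows,
                                 read_recording, resample_canonical,
                                 segment_windows)


def make_csv(tmp_path, times, samples, name="S000.csv"):
    df = pd.DataFrame({
        "time_iso": pd.to_datetime(times).strftime("%Y-%m-%dT%H:%M:%S.%f"),
        "gyro_x": samples[:, 0], "gyro_y": samples[:, 1],
        "gyro_z": samples[:, 2]})
    path = tmp_path / name
    df.to_csv(path, index=False)
    return path


def make_recording(duration_s, fs=100.0, start="2024-01-01T09:00:00",
                   subject="S000", signal=None):
    n = int(duration_s * fs)
    samples = np.zeros((n, 3)) if signal is None else signal
    return GyroRecording(subject, [Segment(pd.Timestamp(start), fs, samples)])


class TestReadRecording:
    def test_fixture_round_trip(self, tmp_path, rng):
        cfg = tk.SimulationConfig(n_subjects=1, fraction_tremor_subjects=1.0,
                                  days_per_subject=1, day_hours=0.1, seed=3,
                                  gap_hours_per_day=0.0)
        recs, truth = tk.simulate_cohort(cfg)
        tk.write_fixture(recs, truth, tmp_path)
        rec = read_recording(tmp_path / f"{recs[0].subject_id}.csv")
        assert len(rec.segments) == len(recs[0].segments)
        np.testing.assert_allclose(rec.segments[0].samples,
                                   recs[0].segments[0].samples, rtol=1e-12)

    def test_gap_splits_into_segments(self, tmp_path):
        t1 = pd.date_range("2024-01-01 09:00", periods=500, freq="10ms")
        t2 = pd.date_range("2024-01-01 09:10", periods=500, freq="10ms")
        times = t1.append(t2)
        path = make_csv(tmp_path, times, np.ones((1000, 3)))
        rec = read_recording(path)
        assert len(rec.segments) == 2
        assert all(abs(s.fs - 100.0) < 0.5 for s in rec.segments)

    def test_jittered_rate_inferred_from_median_interval(self, tmp_path, rng):
        base = np.arange(2000) / 98.7
        jitter = rng.uniform(-5e-4, 5e-4, size=2000)
        times = pd.Timestamp("2024-01-01") + pd.to_timedelta(base + jitter,
                                                             unit="s")
        path = make_csv(tmp_path, times.sort_values(), np.zeros((2000, 3)))
        rec = read_recording(path)
        assert len(rec.segments) == 1
        assert rec.segments[0].fs == pytest.approx(98.7, rel=0.01)
        # canonical target for this rate is 100 Hz
        out = resample_canonical(rec)
        assert out.segments[0].fs == 100.0

    def test_missing_column_raises(self, tmp_path):
        path = tmp_path / "bad.csv"
        pd.DataFrame({"time_iso": ["2024-01-01T00:00:00"],
                      "gyro_x": [0.0]}).to_csv(path, index=False)
        with pytest.raises(FormatError, match="missing columns"):
            read_recording(path)

    def test_non_monotone_time_names_row(self, tmp_path):
        times = pd.to_datetime(["2024-01-01 00:00:00.00",
                                "2024-01-01 00:00:00.02",
                                "2024-01-01 00:00:00.01",
                                "2024-01-01 00:00:00.03"])
        path = make_csv(tmp_path, times, np.zeros((4, 3)))
        with pytest.raises(FormatError, match="row 4"):
            read_recording(path)


class TestResampleCanonical:
    def test_200_hz_downsamples_to_100(self):
        rec = make_recording(60, fs=200.0)
        out = resample_canonical(rec)
        assert out.segments[0].fs == 100.0
        assert len(out.segments[0].samples) == 6000

    def test_50_hz_unchanged(self):
        rec = make_recording(60, fs=50.0, signal=np.arange(9000.0)
                             .reshape(3000, 3))
        out = resample_canonical(rec)
        assert out.segments[0].fs == 50.0
        np.testing.assert_array_equal(out.segments[0].samples,
                                      rec.segments[0].samples)

    def test_below_50_hz_rejected(self):
        with pytest.raises(ValueError, match="unsupported"):
            resample_canonical(make_recording(10, fs=40.0))

    def test_tone_survives_downsampling(self):
        t = np.arange(6000) / 100.0
        sig = np.zeros((6000, 3))
        sig[:, 0] = np.sin(2 * np.pi * 5.0 * t)
        rec = make_recording(60, fs=100.0, signal=sig)
        out = resample_canonical(GyroRecording("S", [Segment(
            pd.Timestamp("2024-01-01"), 100.0, sig)]),
            targets=(50,))
        w = out.segments[0].samples[200:400]  # skip filter edge transient
        psd = tk.welch_psd(w, 50)
        assert tk.peak_frequency(psd) == pytest.approx(5.0, abs=0.5)
        # band-limited RMS preserved within 2%
        rms_in = np.sqrt(np.mean(sig[200:-200, 0] ** 2))
        rms_out = np.sqrt(np.mean(out.segments[0].samples[100:-100, 0] ** 2))
        assert rms_out == pytest.approx(rms_in, rel=0.02)


class TestSegmentWindows:
    @pytest.mark.parametrize("duration,expected", [(60.0, 15), (61.9, 15)])
    def test_floor_division(self, duration, expected):
        windows = segment_windows(make_recording(duration))
        assert len(windows) == expected

    def test_windows_never_span_gaps(self):
        rec = GyroRecording("S", [
            Segment(pd.Timestamp("2024-01-01 09:00"), 100.0, np.zeros((1000, 3))),
            Segment(pd.Timestamp("2024-01-01 10:00"), 100.0, np.zeros((600, 3))),
        ])
        windows = segment_windows(rec)
        assert len(windows) == 2 + 1
        for w in windows:
            end = w.start_time + pd.Timedelta(seconds=4)
            assert any(s.start_time <= w.start_time and end <= s.end_time
                       for s in rec.segments)
        assert coverage_check(rec, windows)

    def test_empty_recording(self):
        assert segment_windows(GyroRecording("S", [])) == []


class TestLabelWindows:
    @staticmethod
    def windows(n=3, start="2024-01-01 09:00:00"):
        rec = make_recording(4.0 * n, start=start)
        return segment_windows(rec)

    def test_exact_half_overlap_is_tremor(self):
        w = self.windows(1)
        t0 = w[0].start_time
        ann = AnnotationTrack([
            (t0, t0 + pd.Timedelta(seconds=2.0), "tremor", True),
            (t0, t0 + pd.Timedelta(seconds=4.0), "activity", "sitting")])
        out = label_windows(w, ann)
        assert out[0].label_tremor is True

    def test_no_tremor_overlap_is_false(self):
        w = self.windows(1)
        t0 = w[0].start_time
        ann = AnnotationTrack([
            (t0 + pd.Timedelta(seconds=10), t0 + pd.Timedelta(seconds=12),
             "tremor", True),
            (t0, t0 + pd.Timedelta(seconds=4), "activity", "sitting")])
        assert label_windows(w, ann)[0].label_tremor is False

    def test_activity_argmax_overlap(self):
        w = self.windows(1)
        t0 = w[0].start_time
        ann = AnnotationTrack([
            (t0, t0 + pd.Timedelta(seconds=2.5), "activity", "sitting"),
            (t0 + pd.Timedelta(seconds=2.5), t0 + pd.Timedelta(seconds=4.0),
             "activity", "gait")])
        assert label_windows(w, ann)[0].label_activity == "sitting"

    def test_uncovered_window_label_null(self):
        w = self.windows(1)
        out = label_windows(w, AnnotationTrack([]))
        assert out[0].label_tremor is None
        assert out[0].label_activity is None

    @settings(derandomize=True, max_examples=20, deadline=None)
    @given(st.permutations(range(4)))
    def test_permutation_invariant(self, order):
        w = self.windows(2)
        t0 = w[0].start_time

        def td(s):
            return t0 + pd.Timedelta(seconds=s)

        base = [(td(0), td(3), "tremor", True),
                (td(0), td(2), "activity", "sitting"),
                (td(2), td(5), "activity", "gait"),
                (td(5), td(8), "activity", "standing")]
        shuffled = AnnotationTrack([base[i] for i in order])
        ref = label_windows(w, AnnotationTrack(base))
        out = label_windows(w, shuffled)
        assert [(x.label_tremor, x.label_activity) for x in out] \
            == [(x.label_tremor, x.label_activity) for x in ref]

    def test_overlapping_activity_intervals_rejected(self):
        t0 = pd.Timestamp("2024-01-01")
        with pytest.raises(ValueError, match="overlapping"):
            AnnotationTrack([
                (t0, t0 + pd.Timedelta(seconds=4), "activity", "sitting"),
                (t0 + pd.Timedelta(seconds=2), t0 + pd.Timedelta(seconds=6),
                 "activity", "gait")])
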