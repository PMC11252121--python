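"""Preprocessing chain: windowing, QC, filtering, segmentation, labels, exclusion."""

import numpy as np
import pytest

from pulsebp import (
    FilterSpec,
    PhysioRecord,
    bandpass,
    extract_labels,
    is_flat_or_missing,
    passes_bp_filter,
    preprocess_record,
    resample_to_fixed,
    segment_two_beats,
    window_record,
)
from pulsebp.preprocess import PreprocessConfig, RejectionTally, Window
from pulsebp.synthetic import synth_abp, synth_ecg, synth_ppg


def _record_of(n_samples, fs=125.0):
    t = np.arange(n_samples) / fs
    wave = np.sin(2 * np.pi * 1.2 * t)
    return PhysioRecord("s", fs, wave, wave.copy(), "II", 80 + 20 * wave)


class TestWindowing:
    @pytest.mark.parametrize(
        "seconds,expected", [(80, 10), (8.5, 1), (7, 0), (16, 2)]
    )
    def test_window_counts(self, seconds, expected):
        rec = _record_of(int(seconds * 125))
        windows = window_record(rec)
        assert len(windows) == expected
        assert all(len(w.ppg) == 1000 for w in windows)

    def test_windows_are_consecutive_and_nonoverlapping(self):
        rec = _record_of(3000)
        offsets = [w.start_offset for w in window_record(rec)]
        assert offsets == [0, 1000, 2000]


class TestFlatOrMissing:
    def test_constant_signal_is_flat(self):
        assert is_flat_or_missing(np.full(1000, 0.7))

    def test_sinusoid_is_not_flat(self):
        assert not is_flat_or_missing(np.sin(np.linspace(0, 20, 1000)))

    def test_single_nan_flags_missing(self):
        x = np.sin(np.linspace(0, 20, 1000))
        x[500] = np.nan
        assert is_flat_or_missing(x)

    def test_tolerance_boundary(self):
        x = np.zeros(100)
        x[0] = 1e-6
        assert is_flat_or_missing(x, flat_tolerance=1e-6)
        x[0] = 1e-5
        assert not is_flat_or_missing(x, flat_tolerance=1e-6)


class TestBandpass:
    fs = 125.0

    def _tone(self, hz, seconds=40):
        t = np.arange(int(seconds * self.fs)) / self.fs
        return np.sin(2 * np.pi * hz * t)

    def test_drift_attenuated_below_10pct(self):
        out = bandpass(self._tone(0.05), self.fs, FilterSpec(0.5, 20.0))
        mid = slice(1000, -1000)  # ignore filter edge transients
        assert np.max(np.abs(out[mid])) < 0.1

    def test_passband_tone_preserved_within_20pct(self):
        out = bandpass(self._tone(5.0), self.fs, FilterSpec(0.5, 20.0))
        mid = slice(1000, -1000)
        assert 0.8 < np.max(np.abs(out[mid])) < 1.2

    def test_zero_in_zero_out(self):
        out = bandpass(np.zeros(1000), self.fs, FilterSpec(0.5, 20.0))
        np.testing.assert_array_equal(out, 0.0)

    def test_same_length_output(self):
        assert len(bandpass(self._tone(3, 10), self.fs, FilterSpec(2, 20))) == 1250

    def test_edge_at_nyquist_rejected(self):
        with pytest.raises(ValueError):
            bandpass(self._tone(3), self.fs, FilterSpec(0.5, 62.5))

    def test_zero_phase_preserves_peak_timing(self):
        # a pulse filtered zero-phase keeps its maximum in place (± 1 sample)
        x = np.zeros(2000)
        x[1000] = 1.0
        out = bandpass(x, self.fs, FilterSpec(0.5, 20.0))
        assert abs(int(np.argmax(out)) - 1000) <= 1


class TestSegmentation:
    def _window(self, n=1000):
        x = np.arange(n, dtype=float)
        return Window(ppg=x, ecg=x + 1, abp=x + 2, fs=125.0, start_offset=0)

    def test_five_peaks_make_three_segments(self):
        segs = segment_two_beats(self._window(), np.array([0, 100, 200, 300, 400]), 125.0)
        assert len(segs) == 3

    def test_rr_intervals_from_peak_spacing(self):
        segs = segment_two_beats(self._window(), np.array([0, 100, 210]), 125.0)
        assert segs[0]["rr1"] == pytest.approx(0.8)
        assert segs[0]["rr2"] == pytest.approx(0.88)

    def test_two_peaks_yield_nothing(self):
        assert segment_two_beats(self._window(), np.array([0, 100]), 125.0) == []

    def test_identical_cut_across_channels_and_duration(self):
        segs = segment_two_beats(self._window(), np.array([10, 110, 230]), 125.0)
        seg = segs[0]
        assert len(seg["ppg"]) == len(seg["ecg"]) == len(seg["abp"]) == 220
        np.testing.assert_array_equal(seg["ecg"], seg["ppg"] + 1)
        assert seg["rr1"] + seg["rr2"] == pytest.approx(220 / 125.0, abs=1 / 125.0)

    def test_peak_outside_window_rejected(self):
        with pytest.raises(ValueError):
            segment_two_beats(self._window(), np.array([0, 100, 1200]), 125.0)


class TestResample:
    def test_identity_at_target_length(self):
        x = np.random.default_rng(0).normal(size=200)
        np.testing.assert_array_equal(resample_to_fixed(x), x)

    def test_two_point_ramp(self):
        out = resample_to_fixed(np.array([0.0, 1.0]))
        np.testing.assert_allclose(out, np.linspace(0, 1, 200))

    def test_ramp_137_points_stays_linear(self):
        out = resample_to_fixed(np.arange(137.0))
        assert out[0] == 0.0 and out[-1] == 136.0
        np.testing.assert_allclose(out, np.linspace(0, 136, 200), atol=1e-9)

    def test_monotone_preserved(self):
        x = np.cumsum(np.random.default_rng(1).random(57))
        out = resample_to_fixed(x)
        assert np.all(np.diff(out) >= 0)

    def test_too_short_errors(self):
        with pytest.raises(ValueError):
            resample_to_fixed(np.array([1.0]))


class TestLabels:
    def test_constant_pressure(self):
        assert extract_labels(np.full(100, 80.0)) == (80.0, 80.0, 0.0)

    def test_oscillating_pressure(self):
        x = 92 + 27 * np.sin(np.linspace(0, 4 * np.pi, 400))
        sbp, dbp, pp = extract_labels(x)
        assert sbp == pytest.approx(119, abs=0.01)
        assert dbp == pytest.approx(65, abs=0.01)
        assert pp == pytest.approx(54, abs=0.02)

    def test_two_beat_segment_takes_global_max(self):
        beats = np.array([0.1, 0.9, 1.7])
        abp = synth_abp(beats, np.array([118.0, 122.0, 120.0]), np.full(3, 70.0), 125.0, 300)
        sbp, _, _ = extract_labels(abp[int(0.1 * 125) : int(1.7 * 125)])
        assert sbp == pytest.approx(122, abs=0.5)

    def test_nonfinite_errors(self):
        with pytest.raises(ValueError):
            extract_labels(np.array([80.0, np.nan]))


class TestBPFilter:
    @pytest.mark.parametrize(
        "sbp,dbp,expected",
        [
            (119, 65, True),
            (210, 95, False),   # systolic above retention ceiling
            (150, 70, False),   # pulse pressure 80 > 70
            (85, 55, False),    # systolic below floor
            (120, 45, False),   # diastolic below floor
            (150, 115, False),  # diastolic above ceiling
            (100, 85, False),   # pulse pressure 15 < 20
            (90, 50, True),     # floors are inclusive
            (160, 110, True),   # diastolic ceiling inclusive
            (90, 70, True),     # pulse-pressure floor inclusive
            (200, 130, False),
        ],
    )
    def test_bounds(self, sbp, dbp, expected):
        assert passes_bp_filter(sbp, dbp, sbp - dbp) is expected


class TestPreprocessRecord:
    fs = 125.0

    def _clean_record(self, seconds=64, rr=0.8, sbp=120.0, dbp=70.0, subject="s"):
        n = int(seconds * self.fs)
        beats = np.arange(0.2, seconds + 1.0, rr)
        ecg = synth_ecg(beats, self.fs, n)
        abp = synth_abp(beats, np.full(len(beats), sbp), np.full(len(beats), dbp), self.fs, n)
        ppg = synth_ppg(beats, np.full(len(beats), 0.25), self.fs, n)
        return PhysioRecord(subject, self.fs, ppg, ecg, "II", abp)

    def test_clean_record_count_matches_beat_schedule(self):
        rec = self._clean_record(seconds=64, rr=0.8)
        tally = RejectionTally()
        segments = preprocess_record(rec, tally=tally)
        # 8 windows; 10 beats per 8-s window => 8 segments per window
        assert tally.windows_total == 8
        assert tally.windows_flat_or_missing == 0
        per_window = [10 - 2] * 8
        assert len(segments) == sum(per_window)
        assert all(passes_bp_filter(s.sbp, s.dbp, s.pp) for s in segments)
        assert all(s.subject_id == "s" for s in segments)

    def test_out_of_range_pressure_excludes_everything(self):
        rec = self._clean_record(sbp=210.0, dbp=95.0)
        assert preprocess_record(rec) == []

    def test_flat_ppg_window_drops_only_that_window(self):
        rec = self._clean_record(seconds=40)
        n_clean = len(preprocess_record(rec))
        rec.ppg[1000:2000] = 0.5  # second window flat
        tally = RejectionTally()
        segments = preprocess_record(rec, tally=tally)
        assert tally.windows_flat_or_missing == 1
        assert len(segments) == n_clean - 8  # one window's worth of segments

    def test_deterministic(self, clean_dataset):
        records, _ = clean_dataset
        a = preprocess_record(records[0])
        b = preprocess_record(records[0])
        assert len(a) == len(b)
        for s1, s2 in zip(a, b):
            np.testing.assert_array_equal(s1.ppg200, s2.ppg200)
            assert s1.sbp == s2.sbp and s1.rr1 == s2.rr1

    def test_segment_invariants_hold(self, clean_segments):
        assert clean_segments, "clean fixture should produce segments"
        for s in clean_segments:
            assert s.ppg200.shape == (200,) and s.ecg200.shape == (200,)
            assert s.rr1 > 0 and s.rr2 > 0
            assert s.pp == pytest.approx(s.sbp - s.dbp)
            assert passes_bp_filter(s.sbp, s.dbp, s.pp)

    def test_two_beat_tiling_mode_halves_segments(self):
        rec = self._clean_record(seconds=64, rr=0.8)
        overlap = preprocess_record(rec)
        cfg = PreprocessConfig(beat_stride=2)
        tiled = preprocess_record(rec, cfg)
        assert len(tiled) == len([s for i, s in enumerate(overlap) if i % 2 == 0])
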