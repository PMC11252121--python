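"""Seven-stage preprocessing chain from raw records to beat segments.

Stages, in order: (1) channel-eligible record in, (2) split into
non-overlapping 8-s windows, (3) reject windows whose PPG or ECG is flat or
contains missing values, (4) zero-phase bandpass (0.5–20 Hz PPG, 2–20 Hz
ECG), (5) Pan–Tompkins R-peak detection on the filtered ECG, (6) two-beat
segmentation cut identically from PPG/ECG/ABP and 200-point linear
interpolation of PPG and ECG, (7) label extraction from the raw ABP
(systolic = max, diastolic = min) and exclusion of segments outside the
retained pressure ranges (SBP 90–200, DBP 50–110, PP 20–70 mmHg).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.signal import butter, sosfiltfilt

from .qrs import PanTompkinsConfig, detect_r_peaks
from .records import BeatSegment, PhysioRecord


@dataclass
class FilterSpec:
    low_hz: float
    high_hz: float
    order: int = 4
    kind: str = "butter"

    def validate(self, fs: float) -> None:
        if not (0 < self.low_hz < self.high_hz):
            raise ValueError(f"invalid passband {self.low_hz}-{self.high_hz} Hz")
        if self.high_hz >= fs / 2:
            raise ValueError(
                f"passband edge {self.high_hz} Hz at or above Nyquist ({fs / 2} Hz)"
            )


PPG_BAND = FilterSpec(0.5, 20.0)
ECG_BAND = FilterSpec(2.0, 20.0)


@dataclass
class Window:
    """One 8-s slice of a record (1000 samples at 125 Hz)."""

    ppg: np.ndarray
    ecg: np.ndarray
    abp: np.ndarray
    fs: float
    start_offset: int


@dataclass
class BPBounds:
    """Inclusive retention ranges for the ABP-derived labels (mmHg)."""

    sbp_min: float = 90.0
    sbp_max: float = 200.0
    dbp_min: float = 50.0
    dbp_max: float = 110.0
    pp_min: float = 20.0
    pp_max: float = 70.0


@dataclass
class PreprocessConfig:
    window_s: float = 8.0
    fs: float = 125.0
    ppg_band: FilterSpec = field(default_factory=lambda: FilterSpec(0.5, 20.0))
    ecg_band: FilterSpec = field(default_factory=lambda: FilterSpec(2.0, 20.0))
    target_len: int = 200
    bounds: BPBounds = field(default_factory=BPBounds)
    flat_tolerance: float = 1e-6
    beat_stride: int = 1  # 1 = overlapping one-beat slide, 2 = tiling
    pan_tompkins: PanTompkinsConfig = field(default_factory=PanTompkinsConfig)


@dataclass
class RejectionTally:
    """Per-stage rejection counters for pipeline auditability."""

    windows_total: int = 0
    windows_flat_or_missing: int = 0
    windows_too_few_peaks: int = 0
    segments_raw: int = 0
    segments_bp_excluded: int = 0
    segments_kept: int = 0


def window_record(record: PhysioRecord, window_s: float = 8.0) -> list[Window]:
    """Cut a record into consecutive non-overlapping windows.

    A trailing remainder shorter than ``window_s`` is discarded; a record
    shorter than one window yields an empty list.
    """
    n = int(round(window_s * record.sampling_rate))
    out = []
    for start in range(0, len(record) - n + 1, n):
        out.append(
            Window(
                ppg=record.ppg[start : start + n],
                ecg=record.ecg[start : start + n],
                abp=record.abp[start : start + n],
                fs=record.sampling_rate,
                start_offset=start,
            )
        )
    return out


def is_flat_or_missing(x: np.ndarray, flat_tolerance: float = 1e-6) -> bool:
    """True iff ``x`` has any non-finite sample or peak-to-peak ≤ tolerance."""
    x = np.asarray(x, dtype=float)
    if x.size == 0:
        raise ValueError("empty signal")
    if not np.all(np.isfinite(x)):
        return True
    return float(np.ptp(x)) <= flat_tolerance


def bandpass(x: np.ndarray, fs: float, spec: FilterSpec) -> np.ndarray:
    """Zero-phase Butterworth bandpass; output length equals input length.

    Forward-backward filtering keeps PPG and ECG free of relative group
    delay, protecting pulse-arrival timing between the channels.
    """
    spec.validate(fs)
    sos = butter(
        spec.order, [spec.low_hz / (fs / 2), spec.high_hz / (fs / 2)],
        btype="band", output="sos",
    )
    return sosfiltfilt(sos, np.asarray(x, dtype=float))


def segment_two_beats(
    window: Window, rpeaks: np.ndarray, fs: float
) -> list[dict]:
    """Cut two-R-R spans [r_i, r_{i+2}) identically from PPG/ECG/ABP.

    Segments slide one beat at a time (consecutive triples of peaks), so a
    window with p peaks yields p − 2 overlapping segments.  Returns raw
    (unresampled) sample spans plus the two R-R intervals in seconds.
    """
    rpeaks = np.asarray(rpeaks, dtype=int)
    if np.any(rpeaks < 0) or np.any(rpeaks >= len(window.ppg)):
        raise ValueError("R peaks outside window bounds")
    out = []
    for i in range(0, len(rpeaks) - 2):
        r0, r1, r2 = rpeaks[i], rpeaks[i + 1], rpeaks[i + 2]
        out.append(
            {
                "ppg": window.ppg[r0:r2],
                "ecg": window.ecg[r0:r2],
                "abp": window.abp[r0:r2],
                "rr1": (r1 - r0) / fs,
                "rr2": (r2 - r1) / fs,
                "start": int(window.start_offset + r0),
            }
        )
    return out


def resample_to_fixed(x: np.ndarray, target_len: int = 200) -> np.ndarray:
    """Linearly interpolate a sequence onto ``target_len`` evenly spaced points.

    Endpoints are preserved exactly and monotone inputs stay monotone.
    """
    x = np.asarray(x, dtype=float)
    if len(x) < 2:
        raise ValueError(f"need at least 2 points to resample, got {len(x)}")
    if len(x) == target_len:
        return x.copy()
    pos = np.linspace(0.0, len(x) - 1.0, target_len)
    return np.interp(pos, np.arange(len(x)), x)


def extract_labels(abp_segment: np.ndarray) -> tuple[float, float, float]:
    """Systolic/diastolic/pulse pressure of an ABP span: (max, min, max−min)."""
    abp_segment = np.asarray(abp_segment, dtype=float)
    if abp_segment.size == 0:
        raise ValueError("empty ABP segment")
    if not np.all(np.isfinite(abp_segment)):
        raise ValueError("non-finite ABP values (should have been rejected by QC)")
    sbp = float(np.max(abp_segment))
    dbp = float(np.min(abp_segment))
    return sbp, dbp, sbp - dbp


def passes_bp_filter(
    sbp: float, dbp: float, pp: float, bounds: BPBounds | None = None
) -> bool:
    """True iff all three pressures fall inside the retained ranges (inclusive)."""
    b = bounds or BPBounds()
    return (
        b.sbp_min <= sbp <= b.sbp_max
        and b.dbp_min <= dbp <= b.dbp_max
        and b.pp_min <= pp <= b.pp_max
    )


def preprocess_record(
    record: PhysioRecord,
    config: PreprocessConfig | None = None,
    tally: RejectionTally | None = None,
) -> list[BeatSegment]:
    """Run the full chain on one record and return surviving beat segments.

    Deterministic: identical records produce identical segment lists.  The
    optional ``tally`` accumulates per-stage rejection counts.
    """
    cfg = config or PreprocessConfig()
    tally = tally if tally is not None else RejectionTally()
    segments: list[BeatSegment] = []
    for window in window_record(record, cfg.window_s):
        tally.windows_total += 1
        # QC: PPG/ECG flat-or-missing per the exclusion rule; non-finite ABP
        # also rejected since pressure labels would be meaningless
        if (
            is_flat_or_missing(window.ppg, cfg.flat_tolerance)
            or is_flat_or_missing(window.ecg, cfg.flat_tolerance)
            or not np.all(np.isfinite(window.abp))
        ):
            tally.windows_flat_or_missing += 1
            continue
        ppg_f = bandpass(window.ppg, cfg.fs, cfg.ppg_band)
        ecg_f = bandpass(window.ecg, cfg.fs, cfg.ecg_band)
        rpeaks = detect_r_peaks(ecg_f, cfg.fs, cfg.pan_tompkins)
        if len(rpeaks) < 3:
            tally.windows_too_few_peaks += 1
            continue
        filtered = Window(
            ppg=ppg_f, ecg=ecg_f, abp=window.abp,
            fs=window.fs, start_offset=window.start_offset,
        )
        raws = segment_two_beats(filtered, rpeaks, cfg.fs)[:: cfg.beat_stride]
        for raw in raws:
            tally.segments_raw += 1
            sbp, dbp, pp = extract_labels(raw["abp"])
            if not passes_bp_filter(sbp, dbp, pp, cfg.bounds):
                tally.segments_bp_excluded += 1
                continue
            segments.append(
                BeatSegment(
                    ppg200=resample_to_fixed(raw["ppg"], cfg.target_len),
                    ecg200=resample_to_fixed(raw["ecg"], cfg.target_len),
                    rr1=raw["rr1"],
                    rr2=raw["rr2"],
                    sbp=sbp,
                    dbp=dbp,
                    pp=pp,
                    subject_id=record.subject_id,
                )
            )
            tally.segments_kept += 1
    return segments
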