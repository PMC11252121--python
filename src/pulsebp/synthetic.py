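"""Synthetic coupled ECG/ABP/PPG records with exact ground truth.

The generator emulates the statistical structure the regression task
assumes: blood pressure information carried by PPG–ECG timing (pulse
arrival time, PAT) and by heart rate.  Per subject, heart rate and PAT
evolve as bounded random walks; each beat's systolic/diastolic pressure
follows an inverse-PAT-plus-heart-rate model

    SBP = a0 + a1 / PAT + a2 * HR + noise     (and analogously for DBP)

echoing pulse-wave-velocity physiology, clamped to the retained pressure
ranges.  Waveform templates are analytic (Gaussian QRS complex,
raised-cosine pressure and volume pulses) so every beat time, PAT and
pressure is known exactly.  Corruption modes (flat 8-s spans, NaN runs,
beats forced outside each pressure bound) exercise every quality-control
and exclusion rule of the preprocessing chain.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .records import PhysioRecord


@dataclass
class BPModel:
    """Coefficients of pressure = a0 + a1/PAT + a2·HR + N(0, noise_sd)."""

    a0: float
    a1: float  # mmHg·s
    a2: float  # mmHg per bpm
    noise_sd: float = 3.0

    def pressure(self, pat: np.ndarray, hr: np.ndarray, rng: np.random.Generator) -> np.ndarray:
        clean = self.a0 + self.a1 / pat + self.a2 * hr
        if self.noise_sd > 0:
            clean = clean + rng.normal(0.0, self.noise_sd, size=np.shape(clean))
        return clean


@dataclass
class CorruptionConfig:
    """Fractions/counts of injected defects; all zero = clean data."""

    flat_ppg_window_frac: float = 0.0   # fraction of 8-s windows with constant PPG
    missing_window_frac: float = 0.0    # fraction of 8-s windows with a NaN run in ECG
    bp_rule_beats: int = 0              # consecutive beats forced past EACH pressure bound


@dataclass
class SynthConfig:
    n_subjects: int = 20
    record_seconds: float = 240.0
    fs: float = 125.0
    hr_range: tuple[float, float] = (60.0, 100.0)     # bpm
    pat_range: tuple[float, float] = (0.20, 0.40)     # s
    sbp_model: BPModel = field(default_factory=lambda: BPModel(40.0, 18.0, 0.15, 3.0))
    dbp_model: BPModel = field(default_factory=lambda: BPModel(30.0, 8.0, 0.08, 3.0))
    sbp_range: tuple[float, float] = (90.0, 180.0)    # clamp, mmHg
    dbp_range: tuple[float, float] = (50.0, 110.0)    # clamp, mmHg
    hr_walk_sd: float = 1.0      # bpm per beat
    pat_walk_sd: float = 0.008   # s per beat
    corruption: CorruptionConfig = field(default_factory=CorruptionConfig)
    seed: int = 0

    def validate(self) -> None:
        for name, (lo, hi) in (
            ("hr_range", self.hr_range),
            ("pat_range", self.pat_range),
            ("sbp_range", self.sbp_range),
            ("dbp_range", self.dbp_range),
        ):
            if not lo < hi:
                raise ValueError(f"{name} is empty: {(lo, hi)}")
        if self.sbp_model.noise_sd < 0 or self.dbp_model.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.fs <= 0:
            raise ValueError("fs must be > 0")


@dataclass
class GroundTruth:
    """Exact per-beat physiology plus corruption bookkeeping."""

    beats: pd.DataFrame  # subject_id, beat_time_s, pat_s, hr_bpm, sbp, dbp, bp_corrupted
    window_flags: pd.DataFrame  # subject_id, window_index, kind

    def for_subject(self, subject_id: str) -> pd.DataFrame:
        return self.beats[self.beats.subject_id == subject_id].reset_index(drop=True)


# ---------------------------------------------------------------------------
# waveform templates


def _add_gaussian(signal: np.ndarray, center_s: float, sigma_s: float,
                  amplitude: float, fs: float) -> None:
    half = 4.0 * sigma_s
    lo = max(0, int(np.floor((center_s - half) * fs)))
    hi = min(len(signal), int(np.ceil((center_s + half) * fs)) + 1)
    if hi <= lo:
        return
    t = np.arange(lo, hi) / fs
    signal[lo:hi] += amplitude * np.exp(-0.5 * ((t - center_s) / sigma_s) ** 2)


def synth_ecg(beat_times: np.ndarray, fs: float, n_samples: int | None = None) -> np.ndarray:
    """Flat baseline with a narrow biphasic QRS template at each beat time.

    The global maximum of each beat lies within one sample of its planted
    time.  Beat spacing below 0.3 s is rejected.
    """
    beat_times = np.asarray(beat_times, dtype=float)
    if beat_times.size and np.any(np.diff(beat_times) < 0.3):
        raise ValueError("beat spacing below 0.3 s")
    if n_samples is None:
        n_samples = int(np.ceil((beat_times.max() + 1.0) * fs)) if beat_times.size else int(fs)
    ecg = np.zeros(n_samples)
    for t in beat_times:
        _add_gaussian(ecg, t - 0.028, 0.012, -0.15, fs)  # Q
        _add_gaussian(ecg, t, 0.011, 1.0, fs)            # R
        _add_gaussian(ecg, t + 0.030, 0.013, -0.25, fs)  # S
        _add_gaussian(ecg, t + 0.18, 0.05, 0.15, fs)     # T
    return ecg


def _abp_pulse(phase: np.ndarray) -> np.ndarray:
    """Normalized pressure pulse on phase [0, 1): 0 → 1 (at 0.25) → 0."""
    rise = 0.5 * (1.0 - np.cos(np.pi * phase / 0.25))
    decay = 0.5 * (1.0 + np.cos(np.pi * (phase - 0.25) / 0.75))
    dicrotic = 0.05 * np.exp(-0.5 * ((phase - 0.45) / 0.05) ** 2)
    out = np.where(phase < 0.25, rise, decay + dicrotic)
    return np.clip(out, 0.0, 1.0)


def synth_abp(
    beat_times: np.ndarray,
    sbp_per_beat: np.ndarray,
    dbp_per_beat: np.ndarray,
    fs: float,
    n_samples: int | None = None,
) -> np.ndarray:
    """Smooth pressure waveform whose per-beat max/min hit SBP/DBP (± 0.5 mmHg)."""
    beat_times = np.asarray(beat_times, dtype=float)
    sbp = np.asarray(sbp_per_beat, dtype=float)
    dbp = np.asarray(dbp_per_beat, dtype=float)
    if np.any(sbp <= dbp):
        raise ValueError("per-beat SBP must exceed DBP")
    if n_samples is None:
        n_samples = int(np.ceil((beat_times.max() + 1.0) * fs))
    t = np.arange(n_samples) / fs
    abp = np.full(n_samples, dbp[0] if dbp.size else 80.0)
    for i, t0 in enumerate(beat_times):
        t1 = beat_times[i + 1] if i + 1 < len(beat_times) else t0 + 0.8
        lo = int(np.ceil(t0 * fs))
        hi = min(n_samples, int(np.ceil(t1 * fs)))
        if hi <= lo:
            continue
        phase = (t[lo:hi] - t0) / (t1 - t0)
        abp[lo:hi] = dbp[i] + (sbp[i] - dbp[i]) * _abp_pulse(phase)
    if beat_times.size:
        abp[t >= beat_times[-1] + 0.8] = dbp[-1]
    return abp


def _ppg_pulse(tau: np.ndarray) -> np.ndarray:
    """Normalized volume pulse vs time-since-foot (s): rise 0.15 s, decay 0.40 s."""
    rise = 0.5 * (1.0 - np.cos(np.pi * tau / 0.15))
    decay = 0.5 * (1.0 + np.cos(np.pi * (tau - 0.15) / 0.40)) + 0.06 * np.exp(
        -0.5 * ((tau - 0.32) / 0.05) ** 2
    )
    out = np.where(tau < 0.15, rise, decay)
    return np.where((tau < 0.0) | (tau > 0.55), 0.0, np.clip(out, 0.0, 1.05))


def synth_ppg(
    beat_times: np.ndarray,
    pat_per_beat: np.ndarray,
    fs: float,
    n_samples: int | None = None,
) -> np.ndarray:
    """Single-peaked pulse per beat whose foot lies PAT seconds after the R time."""
    beat_times = np.asarray(beat_times, dtype=float)
    pat = np.asarray(pat_per_beat, dtype=float)
    if np.any(pat <= 0):
        raise ValueError("PAT must be positive")
    if n_samples is None:
        n_samples = int(np.ceil((beat_times.max() + 1.5) * fs)) if beat_times.size else int(fs)
    ppg = np.zeros(n_samples)
    for t0, p in zip(beat_times, pat):
        foot = t0 + p
        lo = max(0, int(np.floor(foot * fs)))
        hi = min(n_samples, int(np.ceil((foot + 0.55) * fs)) + 1)
        if hi <= lo:
            continue
        tau = np.arange(lo, hi) / fs - foot
        ppg[lo:hi] += _ppg_pulse(tau)
    return ppg


# ---------------------------------------------------------------------------
# dataset generation


def _bounded_walk(rng: np.random.Generator, n: int, lo: float, hi: float,
                  step_sd: float) -> np.ndarray:
    x = np.empty(n)
    x[0] = rng.uniform(lo, hi)
    for i in range(1, n):
        x[i] = np.clip(x[i - 1] + rng.normal(0.0, step_sd), lo, hi)
    return x


# forced (SBP, DBP) pairs, one per exclusion bound
_BP_VIOLATIONS = [
    ("sbp_high", 210.0, 95.0),
    ("dbp_high", 150.0, 115.0),
    ("sbp_low", 85.0, 55.0),
    ("dbp_low", 110.0, 45.0),
    ("pp_high", 175.0, 95.0),
    ("pp_low", 100.0, 85.0),
]


def generate_subject(
    cfg: SynthConfig, subject_id: str, rng: np.random.Generator
) -> tuple[PhysioRecord, pd.DataFrame, pd.DataFrame]:
    """One subject's coupled record plus its per-beat truth and window flags."""
    n_samples = int(round(cfg.record_seconds * cfg.fs))
    # beat schedule from the heart-rate walk
    est_beats = int(cfg.record_seconds * cfg.hr_range[1] / 60.0) + 4
    hr = _bounded_walk(rng, est_beats, *cfg.hr_range, cfg.hr_walk_sd)
    beat_times = np.cumsum(np.concatenate([[0.2], 60.0 / hr[:-1]]))
    keep = beat_times < cfg.record_seconds + 1.0
    beat_times, hr = beat_times[keep], hr[keep]
    n_beats = len(beat_times)
    pat = _bounded_walk(rng, n_beats, *cfg.pat_range, cfg.pat_walk_sd)
    sbp = np.clip(cfg.sbp_model.pressure(pat, hr, rng), *cfg.sbp_range)
    dbp = np.clip(cfg.dbp_model.pressure(pat, hr, rng), *cfg.dbp_range)
    dbp = np.minimum(dbp, sbp - 15.0)  # physiological floor on pulse pressure

    bp_corrupted = np.zeros(n_beats, dtype=bool)
    if cfg.corruption.bp_rule_beats > 0:
        run = cfg.corruption.bp_rule_beats
        spots = np.linspace(2, n_beats - run - 2, len(_BP_VIOLATIONS)).astype(int)
        for (name, s, d), start in zip(_BP_VIOLATIONS, spots):
            sbp[start : start + run] = s
            dbp[start : start + run] = d
            bp_corrupted[start : start + run] = True

    ecg = synth_ecg(beat_times, cfg.fs, n_samples)
    abp = synth_abp(beat_times, sbp, dbp, cfg.fs, n_samples)
    ppg = synth_ppg(beat_times, pat, cfg.fs, n_samples)

    window_len = int(8 * cfg.fs)
    n_windows = n_samples // window_len
    # windows holding pressure-corrupted beats are kept clean so that every
    # exclusion rule remains observable at segment level
    bp_windows = {
        int(t // 8.0) for t in beat_times[bp_corrupted] if t // 8.0 < n_windows
    }
    free = [w for w in range(n_windows) if w not in bp_windows]
    flags = []
    if cfg.corruption.flat_ppg_window_frac > 0 and free:
        n_flat = min(int(round(cfg.corruption.flat_ppg_window_frac * n_windows)), len(free))
        for w in rng.choice(free, size=n_flat, replace=False):
            ppg[w * window_len : (w + 1) * window_len] = 0.42
            flags.append({"subject_id": subject_id, "window_index": int(w), "kind": "flat_ppg"})
    if cfg.corruption.missing_window_frac > 0 and free:
        n_miss = int(round(cfg.corruption.missing_window_frac * n_windows))
        taken = {f["window_index"] for f in flags}
        candidates = [w for w in free if w not in taken]
        for w in rng.choice(candidates, size=min(n_miss, len(candidates)), replace=False):
            start = w * window_len + int(0.3 * window_len)
            ecg[start : start + int(0.2 * window_len)] = np.nan
            flags.append({"subject_id": subject_id, "window_index": int(w), "kind": "missing_ecg"})

    record = PhysioRecord(
        subject_id=subject_id, sampling_rate=cfg.fs,
        ppg=ppg, ecg=ecg, ecg_lead="II", abp=abp,
    )
    beats = pd.DataFrame(
        {
            "subject_id": subject_id,
            "beat_time_s": beat_times,
            "pat_s": pat,
            "hr_bpm": hr,
            "sbp": sbp,
            "dbp": dbp,
            "bp_corrupted": bp_corrupted,
        }
    )
    return record, beats, pd.DataFrame(flags, columns=["subject_id", "window_index", "kind"])


def generate_dataset(cfg: SynthConfig | None = None) -> tuple[list[PhysioRecord], GroundTruth]:
    """Generate all subjects from independent per-subject seed substreams."""
    cfg = cfg or SynthConfig()
    cfg.validate()
    streams = np.random.SeedSequence(cfg.seed).spawn(cfg.n_subjects)
    records, beat_tables, flag_tables = [], [], []
    for i, stream in enumerate(streams):
        rec, beats, flags = generate_subject(
            cfg, f"synth{i:03d}", np.random.default_rng(stream)
        )
        records.append(rec)
        beat_tables.append(beats)
        flag_tables.append(flags)
    truth = GroundTruth(
        beats=pd.concat(beat_tables, ignore_index=True),
        window_flags=pd.concat(flag_tables, ignore_index=True),
    )
    return records, truth


def standard_corruption() -> CorruptionConfig:
    """The audit fixture: fires flat-window, missing-value and all six BP bounds."""
    return CorruptionConfig(
        flat_ppg_window_frac=0.10,
        missing_window_frac=0.05,
        bp_rule_beats=4,
    )
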