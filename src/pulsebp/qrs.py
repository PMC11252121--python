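"""Pan–Tompkins QRS detection.

The classic real-time detector: band-limited differentiation, squaring,
moving-window integration, then adaptive dual thresholds on the integrated
signal with a refractory period and a search-back pass for missed beats.
Detected integration peaks are refined to the R-peak sample by locating the
absolute ECG maximum in a short neighbourhood.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal import butter, lfilter, sosfiltfilt


@dataclass
class PanTompkinsConfig:
    refractory_s: float = 0.2      # physiological lower bound on R-R
    integration_s: float = 0.15    # moving-window integrator width
    learn_s: float = 2.0           # initial threshold learning span
    band: tuple[float, float] = (5.0, 15.0)  # QRS-emphasis passband
    refine_s: float = 0.075        # half-width of the R-refinement window
    tmin_frac: float = 0.25        # floor on thresholds vs learned peak level


def _moving_window_integral(x: np.ndarray, width: int) -> np.ndarray:
    kernel = np.ones(width) / width
    return np.convolve(x, kernel, mode="same")


def detect_r_peaks(
    ecg: np.ndarray,
    fs: float,
    config: PanTompkinsConfig | None = None,
) -> np.ndarray:
    """Return strictly increasing R-peak sample indices in ``ecg``.

    ``ecg`` is expected to be the bandpassed ECG from the preprocessing
    chain; the detector applies its own 5–15 Hz QRS-emphasis filter on top,
    so raw ECG also works.  May return an empty array (e.g. a flat signal).
    """
    cfg = config or PanTompkinsConfig()
    ecg = np.asarray(ecg, dtype=float)
    if len(ecg) < 2 * fs:
        raise ValueError(f"need at least 2 s of ECG, got {len(ecg) / fs:.2f} s")
    if not np.all(np.isfinite(ecg)):
        return np.array([], dtype=int)
    if np.ptp(ecg) == 0.0:
        return np.array([], dtype=int)

    low, high = cfg.band
    sos = butter(2, [low / (fs / 2), high / (fs / 2)], btype="band", output="sos")
    band = sosfiltfilt(sos, ecg)

    # five-point band-limited derivative (1/8)(2x[n] + x[n-1] - x[n-3] - 2x[n-4])
    b = np.array([2, 1, 0, -1, -2]) * (fs / 8.0)
    deriv = lfilter(b, [1.0], band)
    squared = deriv**2
    mwi = _moving_window_integral(squared, max(1, int(round(cfg.integration_s * fs))))

    refractory = int(round(cfg.refractory_s * fs))
    # candidate local maxima of the integrated signal
    cand = np.flatnonzero(
        (mwi[1:-1] > mwi[:-2]) & (mwi[1:-1] >= mwi[2:])
    ) + 1
    if cand.size == 0:
        return np.array([], dtype=int)

    learn = mwi[: max(refractory, int(cfg.learn_s * fs))]
    spk = float(np.max(learn))          # running signal-peak estimate
    npk = float(np.mean(learn)) * 0.5   # running noise-peak estimate
    thr1 = npk + 0.25 * (spk - npk)
    peak_floor = cfg.tmin_frac * spk

    accepted: list[int] = []
    last = -refractory
    for idx in cand:
        peak = mwi[idx]
        if idx - last < refractory:
            continue
        if peak >= thr1:
            # search-back: if the gap since the last beat exceeds 1.66x the
            # running R-R estimate, rescan it at the lower threshold thr2
            if len(accepted) >= 2:
                rr_avg = np.mean(np.diff(accepted[-8:]))
                if idx - last > 1.66 * rr_avg:
                    thr2 = 0.5 * thr1
                    window = cand[(cand > last + refractory) & (cand < idx - refractory)]
                    if window.size:
                        back = window[np.argmax(mwi[window])]
                        if mwi[back] >= thr2:
                            accepted.append(int(back))
                            spk = 0.25 * mwi[back] + 0.75 * spk
                            last = back
                            if idx - last < refractory:
                                continue
            accepted.append(int(idx))
            last = idx
            spk = 0.125 * peak + 0.875 * spk
        else:
            npk = 0.125 * peak + 0.875 * npk
        thr1 = max(npk + 0.25 * (spk - npk), peak_floor * 0.1)

    if not accepted:
        return np.array([], dtype=int)

    # refine each integration peak to the true R sample: the absolute
    # maximum of the QRS-band signal nearby (sign-corrected for lead polarity)
    half = int(round(cfg.refine_s * fs))
    refined: list[int] = []
    for idx in accepted:
        lo = max(0, idx - half)
        hi = min(len(ecg), idx + half + 1)
        seg = band[lo:hi]
        r = lo + int(np.argmax(np.abs(seg)))
        refined.append(r)
    out = np.array(sorted(set(refined)), dtype=int)
    # enforce refractory after refinement (keep the larger peak of a close pair)
    keep: list[int] = []
    for r in out:
        if keep and r - keep[-1] < refractory:
            if np.abs(band[r]) > np.abs(band[keep[-1]]):
                keep[-1] = int(r)
        else:
            keep.append(int(r))
    return np.array(keep, dtype=int)
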