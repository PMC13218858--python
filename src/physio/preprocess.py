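"""Per-modality signal conditioning and fiducial detection.

Processing order is fixed: z-score normalization (per participant, over the
full recording, to remove individual differences) -> baseline removal or
band filtering -> fiducial detection.  All filters are zero-phase
(forward-backward 2nd-order Butterworth) so detected fiducial times are not
shifted.

ECG beats are found with a Pan-Tompkins detector (band-pass, derivative,
squaring, moving-window integration, adaptive dual thresholds with
search-back), respiratory cycles with an exhaled-excursion acceptance rule
(a cycle counts only if its exhaled excursion reaches 65% of the running
median excursion), and EMG is decimated to 32 Hz behind a 16 Hz
anti-aliasing filter.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.ndimage import median_filter, uniform_filter1d
from scipy.signal import butter, find_peaks, resample_poly, sosfiltfilt


@dataclass
class RRSeries:
    """R-peak times/amplitudes and the RR intervals between them."""

    r_peak_times: np.ndarray   # s, strictly increasing
    r_amplitudes: np.ndarray   # normalized ECG value at each peak
    rr_intervals: np.ndarray   # s, successive differences of peak times

    def __post_init__(self) -> None:
        if np.any(np.diff(self.r_peak_times) <= 0):
            raise ValueError("R-peak times must be strictly increasing")
        if len(self.rr_intervals) != max(len(self.r_peak_times) - 1, 0):
            raise ValueError("len(rr) must equal len(peaks) - 1")


@dataclass
class BreathCycleSeries:
    """Respiratory cycles delimited at inspiration onsets."""

    onsets: np.ndarray        # s, inspiration-onset (trough) times
    depths: np.ndarray        # amplitude units, peak minus onset trough
    periods: np.ndarray       # s, onset-to-onset duration of each cycle
    inhale_times: np.ndarray  # s, onset-to-peak duration

    def __len__(self) -> int:
        return len(self.onsets)


def zscore(x) -> np.ndarray:
    """Z-score with population SD; a constant input maps to all zeros."""
    x = np.asarray(x, float)
    if x.size < 2:
        raise ValueError("zscore requires at least 2 samples")
    sd = x.std()
    if sd == 0:
        return np.zeros_like(x)
    return (x - x.mean()) / sd


def ecg_remove_baseline(ecg, fs: float = 1000.0) -> np.ndarray:
    """Remove ECG baseline drift with a 200 ms / 600 ms median cascade.

    The baseline estimate is ``median(median(x, 200 ms), 600 ms)``; the
    return value is the input minus that estimate.  QRS complexes (~80 ms)
    are much narrower than the first window and pass through essentially
    unattenuated, while respiratory/motion drift is tracked and removed.
    """
    ecg = np.asarray(ecg, float)
    w1 = int(round(0.200 * fs)) | 1
    w2 = int(round(0.600 * fs)) | 1
    if len(ecg) <= w2:
        raise ValueError("input shorter than the 600 ms median window")
    baseline = median_filter(ecg, size=w1, mode="nearest")
    baseline = median_filter(baseline, size=w2, mode="nearest")
    return ecg - baseline


def _butter_zero_phase(x, fs, btype, edges, order=2) -> np.ndarray:
    sos = butter(order, edges, btype=btype, fs=fs, output="sos")
    return sosfiltfilt(sos, x)


def eda_highpass(eda, fs: float = 1000.0) -> np.ndarray:
    """Zero-phase 2nd-order Butterworth high-pass at 0.02 Hz."""
    eda = np.asarray(eda, float)
    if len(eda) < 10 * fs:
        raise ValueError("EDA input shorter than 10 s")
    return _butter_zero_phase(eda, fs, "high", 0.02)


def rsp_bandpass(rsp, fs: float = 1000.0) -> np.ndarray:
    """Zero-phase 2nd-order Butterworth band-pass 0.1-5 Hz."""
    rsp = np.asarray(rsp, float)
    if len(rsp) < 10 * fs:
        raise ValueError("RSP input shorter than 10 s")
    return _butter_zero_phase(rsp, fs, "band", (0.1, 5.0))


def emg_downsample(emg, fs: float = 1000.0, target_fs: float = 32.0
                   ) -> np.ndarray:
    """Anti-aliased decimation to 32 Hz (length = floor(n*32/1000))."""
    emg = np.asarray(emg, float)
    up, down = int(target_fs), int(fs)
    out = resample_poly(emg, up, down)
    n_out = int(len(emg) * target_fs // fs)
    return out[:n_out]


def pan_tompkins(ecg, fs: float = 1000.0) -> RRSeries:
    """Pan-Tompkins QRS detection on baseline-removed, z-scored ECG.

    Stage chain: 5-15 Hz band-pass, derivative, squaring, 150 ms
    moving-window integration, then adaptive dual thresholds with a 200 ms
    refractory period and RR-based search-back.  Each detection is refined
    to the local ECG maximum within +/-50 ms.
    """
    ecg = np.asarray(ecg, float)
    if len(ecg) < 3 * fs:
        raise ValueError("insufficient beats")
    bp = _butter_zero_phase(ecg, fs, "band", (5.0, 15.0))
    deriv = np.gradient(bp) * fs
    sq = deriv ** 2
    mwi = uniform_filter1d(sq, size=int(round(0.150 * fs)), mode="nearest")

    refractory = int(round(0.200 * fs))
    cand, _ = find_peaks(mwi, distance=refractory)
    if len(cand) < 2:
        raise ValueError("insufficient beats")

    # robust threshold initialization: candidate-peak heights are bimodal
    # (noise vs. QRS), so upper/lower quartiles track the two populations
    # without being poisoned by filter edge transients
    heights = mwi[cand]
    spki = float(np.percentile(heights, 75))
    npki = float(np.percentile(heights, 25))
    accepted: list[int] = []
    missed: list[int] = []
    rr_hist: list[float] = []

    def threshold() -> float:
        return npki + 0.25 * (spki - npki)

    for p in cand:
        val = mwi[p]
        if val > threshold():
            spki = 0.125 * val + 0.875 * spki
            if accepted:
                rr_hist.append((p - accepted[-1]) / fs)
                rr_hist[:] = rr_hist[-8:]
            accepted.append(int(p))
            missed.clear()
        else:
            npki = 0.125 * val + 0.875 * npki
            missed.append(int(p))
            # search-back when the expected beat is overdue
            if accepted:
                avg_rr = float(np.mean(rr_hist)) if rr_hist else 1.0
                if (p - accepted[-1]) / fs > 1.66 * avg_rr:
                    back = [m for m in missed
                            if mwi[m] > 0.5 * threshold()
                            and m - accepted[-1] > refractory]
                    if back:
                        best = max(back, key=lambda m: mwi[m])
                        spki = 0.25 * mwi[best] + 0.75 * spki
                        rr_hist.append((best - accepted[-1]) / fs)
                        rr_hist[:] = rr_hist[-8:]
                        accepted.append(best)
                        accepted.sort()
                        missed.clear()

    if len(accepted) < 2:
        raise ValueError("insufficient beats")

    # refine to the local raw-ECG maximum within +/-50 ms
    half = int(round(0.050 * fs))
    refined = []
    for p in accepted:
        lo, hi = max(0, p - half), min(len(ecg), p + half + 1)
        refined.append(lo + int(np.argmax(ecg[lo:hi])))
    refined = np.unique(refined)
    # enforce the refractory period on refined positions
    keep = [int(refined[0])]
    for p in refined[1:]:
        if p - keep[-1] >= refractory:
            keep.append(int(p))
        elif ecg[p] > ecg[keep[-1]]:
            keep[-1] = int(p)
    peaks = np.asarray(keep)
    if len(peaks) < 2:
        raise ValueError("insufficient beats")
    times = peaks / fs
    return RRSeries(
        r_peak_times=times,
        r_amplitudes=ecg[peaks],
        rr_intervals=np.diff(times),
    )


def detect_breaths(rsp_filtered, fs: float = 1000.0,
                   exhale_frac: float = 0.65) -> BreathCycleSeries:
    """Segment respiratory cycles with a relative exhaled-volume threshold.

    Candidate cycles are trough -> peak -> trough excursion pairs from the
    alternating extrema of the filtered signal.  A candidate is accepted
    only if its exhaled excursion (peak minus following trough) reaches
    ``exhale_frac`` times the running median excursion, suppressing
    low-amplitude oscillations that are not true breaths.  An empty series
    (no accepted cycles) is a valid result, not an error.
    """
    x = np.asarray(rsp_filtered, float)
    empty = BreathCycleSeries(*(np.empty(0) for _ in range(4)))
    span = float(x.max() - x.min()) if x.size else 0.0
    if span <= 0 or x.size < fs:
        return empty
    min_dist = int(round(0.5 * fs))
    floor = 0.02 * span
    peaks, _ = find_peaks(x, distance=min_dist, prominence=floor)
    troughs, _ = find_peaks(-x, distance=min_dist, prominence=floor)
    if len(peaks) == 0 or len(troughs) < 2:
        return empty

    # merge into a strictly alternating extrema sequence, keeping the more
    # extreme of consecutive same-type candidates
    ext = sorted([(int(i), +1) for i in peaks] + [(int(i), -1) for i in troughs])
    alt: list[tuple[int, int]] = []
    for i, kind in ext:
        if alt and alt[-1][1] == kind:
            prev = alt[-1][0]
            better = x[i] > x[prev] if kind > 0 else x[i] < x[prev]
            if better:
                alt[-1] = (i, kind)
        else:
            alt.append((i, kind))

    onsets, depths, periods, inhales = [], [], [], []
    excursions: list[float] = []
    for j in range(len(alt) - 2):
        i_on, k0 = alt[j]
        i_pk, k1 = alt[j + 1]
        i_off, k2 = alt[j + 2]
        if not (k0 < 0 < k1 and k2 < 0):
            continue
        exhaled = float(x[i_pk] - x[i_off])
        excursions.append(exhaled)
        if exhaled < exhale_frac * float(np.median(excursions)):
            continue
        onsets.append(i_on / fs)
        depths.append(float(x[i_pk] - x[i_on]))
        periods.append((i_off - i_on) / fs)
        inhales.append((i_pk - i_on) / fs)
    return BreathCycleSeries(
        onsets=np.asarray(onsets),
        depths=np.asarray(depths),
        periods=np.asarray(periods),
        inhale_times=np.asarray(inhales),
    )
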