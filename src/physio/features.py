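"""Windowed 80-feature extraction across the five modalities.

Features are computed per consecutive non-overlapping 10 s window inside
each annotated event (10 s width, 10 s offset; incomplete tails dropped).
The canonical inventory has 80 named features: 31 ECG (RR/heart-rate
statistics, R-peak amplitude statistics, and VLF/LF/HF spectral power and
density of the 8 Hz cubic-spline-resampled RR tachogram over a 32 s /
256-sample FFT frame), 12 RSP (per-cycle depth/period statistics and their
first differences), 8 TEMP (amplitude and first-difference statistics),
12 EDA (time-domain phasic-event counts and frequency-domain counts,
power and density in LF/HF/VHF bands) and 17 EMG (6-level Daubechies-5
wavelet sub-band energies, absolute and proportional, plus grouped
proportions).

Missing values (too few beats or breath cycles in a window, insufficient
tachogram coverage, zero-energy EMG) are propagated as NaN and never
silently imputed here.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import pywt
from scipy.interpolate import CubicSpline
from scipy.stats import median_abs_deviation

from . import preprocess as pp
from .segmentation import EventSegment, MultichannelRecording, extract_events

log = logging.getLogger(__name__)


@dataclass
class WindowSpec:
    width: float = 10.0   # s
    offset: float = 10.0  # s

    def __post_init__(self) -> None:
        if self.width <= 0 or self.offset <= 0:
            raise ValueError("window width and offset must be positive")


@dataclass
class SpectralBandsECG:
    """HRV bands on the resampled RR tachogram."""

    vlf: tuple[float, float] = (0.0, 0.04)
    lf: tuple[float, float] = (0.04, 0.15)
    hf: tuple[float, float] = (0.15, 0.4)
    resample_rate: float = 8.0    # Hz
    frame_seconds: float = 32.0   # -> 256-sample FFT frame
    min_coverage_s: float = 16.0

    @property
    def n_fft(self) -> int:
        return int(round(self.resample_rate * self.frame_seconds))


@dataclass
class SpectralBandsEDA:
    lf: tuple[float, float] = (0.02, 0.5)
    hf: tuple[float, float] = (0.5, 1.0)
    vhf_low: float = 1.0  # VHF extends to Nyquist


@dataclass
class FeatureConfig:
    window: WindowSpec = field(default_factory=WindowSpec)
    ecg_bands: SpectralBandsECG = field(default_factory=SpectralBandsECG)
    eda_bands: SpectralBandsEDA = field(default_factory=SpectralBandsEDA)
    theta_t: float = 0.05  # z-units, time-domain peak prominence threshold
    theta_f: float = 0.1   # fraction of max in-band bin power
    exhale_frac: float = 0.65


ECG_FEATURES = [
    "RR mean", "RR std", "RR mad", "RR median", "RR min", "RR max", "bpm",
    "RRdiff mean", "RRdiff std", "RRdiff mad", "RMSSD", "pNN20", "pNN50",
    "R mean", "R std", "R mad", "Rdiff mean", "Rdiff std",
    "pwr VLF", "pwr LF", "pwr HF", "pwr TP",
    "psd VLF", "psd LF", "psd HF", "psd TP",
    "LF/HF ratio", "LF norm", "HF norm", "peak-freq LF", "peak-freq HF",
]
RSP_FEATURES = [
    "val mean", "val std", "val mad", "prd mean", "prd std", "prd mad",
    "Diffval mean", "Diffval std", "Diffprd mean", "Diffprd std",
    "breath rate", "duty ratio",
]
TEMP_FEATURES = [
    "temp mean", "temp std", "temp mad", "temp min", "temp max",
    "temp Diff mean", "temp Diff std", "temp Diff mad",
]
EDA_FEATURES = [
    f"{band} {kind}"
    for band in ("LF", "HF", "VHF")
    for kind in ("time sam", "frq sam", "frq pwr", "frq psd")
]
_EMG_BANDS = ["d1", "d2", "d3", "d4", "d5", "d6", "a6"]
EMG_FEATURES = (
    ["Total Eng"]
    + [f"{b} Eng" for b in _EMG_BANDS]
    + [f"{b} Eng%" for b in _EMG_BANDS]
    + ["1-2 level Eng%", "5-6 level (7) Eng%"]
)

#: canonical 80-feature inventory, in canonical column order
FEATURE_NAMES = (
    ECG_FEATURES + RSP_FEATURES + TEMP_FEATURES + EDA_FEATURES + EMG_FEATURES
)
FEATURE_MODALITY = {
    **{f: "ECG" for f in ECG_FEATURES},
    **{f: "RSP" for f in RSP_FEATURES},
    **{f: "TEMP" for f in TEMP_FEATURES},
    **{f: "EDA" for f in EDA_FEATURES},
    **{f: "EMG" for f in EMG_FEATURES},
}
META_COLUMNS = ["participant_id", "condition", "event_id", "window_index"]

assert len(FEATURE_NAMES) == 80


def feature_subset(drop_modalities: tuple[str, ...] = ()) -> list[str]:
    """Canonical feature names with whole modalities removed (ablations)."""
    return [f for f in FEATURE_NAMES
            if FEATURE_MODALITY[f] not in drop_modalities]


def make_windows(duration: float, spec: WindowSpec | None = None
                 ) -> list[tuple[float, float]]:
    """Consecutive [k*offset, k*offset + width) windows fully inside
    ``[0, duration]``; the incomplete tail is dropped."""
    spec = spec or WindowSpec()
    if duration + 1e-9 < spec.width:
        return []
    n = int((duration - spec.width) / spec.offset + 1 + 1e-9)
    return [(i * spec.offset, i * spec.offset + spec.width)
            for i in range(n)]


def _mad(x: np.ndarray) -> float:
    return float(median_abs_deviation(x, scale=1.0))


def _stats_block(prefix_map: dict[str, float], x: np.ndarray,
                 names: tuple[str, ...]) -> None:
    fns = {"mean": np.mean, "std": np.std, "mad": _mad,
           "median": np.median, "min": np.min, "max": np.max}
    for n in names:
        key, stat = n.rsplit(" ", 1)
        prefix_map[n] = float(fns[stat](x)) if len(x) else np.nan


# ---------------------------------------------------------------------------
# per-modality window features
# ---------------------------------------------------------------------------

def ecg_time_features(rr: pp.RRSeries, window: tuple[float, float]
                      ) -> dict[str, float]:
    """Time-domain HRV and R-amplitude statistics for beats in `window`.

    Requires at least 3 in-window beats (2 RR intervals); otherwise every
    time-domain ECG feature is NaN.  ``bpm`` is the mean of the per-beat
    instantaneous rates 60/RR_i, which exceeds 60/(RR mean) whenever RR
    varies (Jensen's inequality).
    """
    lo, hi = window
    mask = (rr.r_peak_times >= lo) & (rr.r_peak_times < hi)
    names = [n for n in ECG_FEATURES if not _is_ecg_freq(n)]
    if mask.sum() < 3:
        return {n: np.nan for n in names}
    times = rr.r_peak_times[mask]
    amps = rr.r_amplitudes[mask]
    rrs = np.diff(times)
    drr = np.diff(rrs)
    out: dict[str, float] = {}
    _stats_block(out, rrs, ("RR mean", "RR std", "RR mad", "RR median",
                            "RR min", "RR max"))
    out["bpm"] = float(np.mean(60.0 / rrs))
    if len(drr):
        _stats_block(out, drr, ("RRdiff mean", "RRdiff std", "RRdiff mad"))
        out["RMSSD"] = float(np.sqrt(np.mean(drr ** 2)))
        out["pNN20"] = float(np.mean(np.abs(drr) > 0.020))
        out["pNN50"] = float(np.mean(np.abs(drr) > 0.050))
    else:
        for n in ("RRdiff mean", "RRdiff std", "RRdiff mad",
                  "RMSSD", "pNN20", "pNN50"):
            out[n] = np.nan
    _stats_block(out, amps, ("R mean", "R std", "R mad"))
    da = np.diff(amps)
    _stats_block(out, da, ("Rdiff mean", "Rdiff std"))
    return out


_ECG_FREQ_NAMES = [
    "pwr VLF", "pwr LF", "pwr HF", "pwr TP",
    "psd VLF", "psd LF", "psd HF", "psd TP",
    "LF/HF ratio", "LF norm", "HF norm", "peak-freq LF", "peak-freq HF",
]


def _is_ecg_freq(name: str) -> bool:
    return name in _ECG_FREQ_NAMES


def ecg_freq_features(rr: pp.RRSeries, window: tuple[float, float],
                      event_bounds: tuple[float, float],
                      bands: SpectralBandsECG | None = None
                      ) -> dict[str, float]:
    """Band powers/densities of the RR tachogram around one window.

    A 32 s analysis frame is centered on the 10 s window and clipped to the
    event; the RR series (interval value attributed to the time of the
    closing beat) is resampled to 8 Hz by cubic spline over beat times,
    mean-removed, zero-padded to 256 samples and Fourier transformed.
    Band power is the one-sided sum of squared spectral magnitudes; PSD is
    power over bandwidth; total power is the sum of the three band powers
    by construction.  Frames with under 16 s of beat coverage yield NaN.
    """
    bands = bands or SpectralBandsECG()
    missing = {n: np.nan for n in _ECG_FREQ_NAMES}
    center = 0.5 * (window[0] + window[1])
    f_lo = max(event_bounds[0], center - bands.frame_seconds / 2)
    f_hi = min(event_bounds[1], center + bands.frame_seconds / 2)
    if len(rr.r_peak_times) < 5:
        return missing
    t_rr = rr.r_peak_times[1:]          # closing-beat convention
    v_rr = rr.rr_intervals
    mask = (t_rr >= f_lo) & (t_rr < f_hi)
    if mask.sum() < 5:
        return missing
    t_in, v_in = t_rr[mask], v_rr[mask]
    if t_in[-1] - t_in[0] < bands.min_coverage_s:
        return missing

    grid = f_lo + np.arange(int(round((f_hi - f_lo) * bands.resample_rate))) \
        / bands.resample_rate
    spline = CubicSpline(t_in, v_in)
    tach = np.where((grid >= t_in[0]) & (grid <= t_in[-1]),
                    spline(grid), np.mean(v_in))
    tach = tach - tach.mean()
    frame = np.zeros(bands.n_fft)
    frame[: min(len(tach), bands.n_fft)] = tach[: bands.n_fft]

    spec = np.fft.rfft(frame)
    power = np.abs(spec) ** 2
    freqs = np.fft.rfftfreq(bands.n_fft, d=1.0 / bands.resample_rate)

    def band_bins(band: tuple[float, float]) -> np.ndarray:
        lo, hi = band
        if lo == 0.0:
            return (freqs <= hi)
        return (freqs > lo) & (freqs <= hi)

    out: dict[str, float] = {}
    for name, band in (("VLF", bands.vlf), ("LF", bands.lf), ("HF", bands.hf)):
        sel = band_bins(band)
        out[f"pwr {name}"] = float(power[sel].sum())
        out[f"psd {name}"] = out[f"pwr {name}"] / (band[1] - band[0])
        in_band = np.where(sel)[0]
        out[f"_peak {name}"] = (
            float(freqs[in_band[np.argmax(power[in_band])]])
            if len(in_band) else np.nan
        )
    out["pwr TP"] = out["pwr VLF"] + out["pwr LF"] + out["pwr HF"]
    out["psd TP"] = out["pwr TP"] / (bands.hf[1] - bands.vlf[0])
    lf, hf = out["pwr LF"], out["pwr HF"]
    out["LF/HF ratio"] = lf / hf if hf > 0 else np.nan
    out["LF norm"] = lf / (lf + hf) if lf + hf > 0 else np.nan
    out["HF norm"] = hf / (lf + hf) if lf + hf > 0 else np.nan
    out["peak-freq LF"] = out.pop("_peak LF")
    out["peak-freq HF"] = out.pop("_peak HF")
    out.pop("_peak VLF")
    return out


def rsp_features(breaths: pp.BreathCycleSeries, window: tuple[float, float]
                 ) -> dict[str, float]:
    """Depth/period statistics of breath cycles whose onset is in `window`.

    Requires at least 2 in-window cycles; otherwise NaN.
    """
    lo, hi = window
    mask = (breaths.onsets >= lo) & (breaths.onsets < hi)
    if mask.sum() < 2:
        return {n: np.nan for n in RSP_FEATURES}
    val = breaths.depths[mask]
    prd = breaths.periods[mask]
    inh = breaths.inhale_times[mask]
    out: dict[str, float] = {}
    _stats_block(out, val, ("val mean", "val std", "val mad"))
    _stats_block(out, prd, ("prd mean", "prd std", "prd mad"))
    dval, dprd = np.diff(val), np.diff(prd)
    _stats_block(out, dval, ("Diffval mean", "Diffval std"))
    _stats_block(out, dprd, ("Diffprd mean", "Diffprd std"))
    out["breath rate"] = 60.0 * mask.sum() / (hi - lo)
    out["duty ratio"] = float(np.mean(inh / prd))
    return out


def temp_features(temp: np.ndarray, fs: float,
                  window: tuple[float, float]) -> dict[str, float]:
    """Amplitude and first-difference statistics of in-window temperature."""
    i0, i1 = int(round(window[0] * fs)), int(round(window[1] * fs))
    x = np.asarray(temp[i0:i1], float)
    out: dict[str, float] = {}
    _stats_block(out, x, ("temp mean", "temp std", "temp mad",
                          "temp min", "temp max"))
    dx = np.diff(x)
    _stats_block(out, dx, ("temp Diff mean", "temp Diff std", "temp Diff mad"))
    return out


def emg_wavelet_features(emg32: np.ndarray, fs32: float = 32.0,
                         wavelet: str = "db5", level: int = 6
                         ) -> dict[str, float]:
    """Sub-band energies of a 6-level Daubechies-5 decomposition.

    Uses periodized boundary handling so the orthogonal transform conserves
    the window's energy exactly: the sub-band energies d1..d6, a6 sum to
    the signal's sum of squares.  Proportional features are NaN for a
    zero-energy window.
    """
    x = np.asarray(emg32, float)
    with warnings.catch_warnings():
        # six levels on a 320-sample window trips pywt's boundary-effect
        # warning; periodization keeps the transform orthogonal regardless
        warnings.simplefilter("ignore", UserWarning)
        coeffs = pywt.wavedec(x, wavelet, level=level, mode="periodization")
    # wavedec returns [a6, d6, d5, ..., d1]
    eng = {"a6": float(np.sum(coeffs[0] ** 2))}
    for i, b in enumerate(range(level, 0, -1)):
        eng[f"d{b}"] = float(np.sum(coeffs[i + 1] ** 2))
    total = sum(eng.values())
    out = {"Total Eng": total}
    for b in _EMG_BANDS:
        out[f"{b} Eng"] = eng[b]
    if total > 0:
        for b in _EMG_BANDS:
            out[f"{b} Eng%"] = eng[b] / total
        out["1-2 level Eng%"] = out["d1 Eng%"] + out["d2 Eng%"]
        out["5-6 level (7) Eng%"] = (
            out["d5 Eng%"] + out["d6 Eng%"] + out["a6 Eng%"]
        )
    else:
        for n in [f"{b} Eng%" for b in _EMG_BANDS] + \
                ["1-2 level Eng%", "5-6 level (7) Eng%"]:
            out[n] = np.nan
    return out


def eda_features(eda_window: np.ndarray,
                 band_windows: dict[str, np.ndarray],
                 fs: float,
                 config: FeatureConfig | None = None) -> dict[str, float]:
    """Time- and frequency-domain EDA features for one window.

    `eda_window` is the high-passed, z-scored signal in the window;
    `band_windows` maps band name (LF/HF/VHF) to the band-limited signal in
    the same window.  "time sam" counts local maxima of the band-limited
    signal with prominence >= theta_t; "frq sam" counts FFT bins of the
    window whose power exceeds theta_f times the largest in-band bin;
    "frq pwr"/"frq psd" are summed band power and power per Hz.
    """
    from scipy.signal import find_peaks

    config = config or FeatureConfig()
    bands = config.eda_bands
    nyq = fs / 2.0
    edges = {"LF": bands.lf, "HF": bands.hf, "VHF": (bands.vhf_low, nyq)}
    n = len(eda_window)
    power = np.abs(np.fft.rfft(eda_window)) ** 2 if n else np.empty(0)
    freqs = np.fft.rfftfreq(n, d=1.0 / fs)
    out: dict[str, float] = {}
    for name, (lo, hi) in edges.items():
        bw = band_windows[name]
        if bw.size and bw.max() - bw.min() > 0:
            peaks, _ = find_peaks(bw, prominence=config.theta_t)
            out[f"{name} time sam"] = float(len(peaks))
        else:
            out[f"{name} time sam"] = 0.0
        sel = (freqs > lo) & (freqs <= hi)
        p_band = power[sel]
        pwr = float(p_band.sum())
        out[f"{name} frq pwr"] = pwr
        out[f"{name} frq psd"] = pwr / (hi - lo)
        if p_band.size and p_band.max() > 0:
            out[f"{name} frq sam"] = float(
                np.sum(p_band > config.theta_f * p_band.max()))
        else:
            out[f"{name} frq sam"] = 0.0
    return out


# ---------------------------------------------------------------------------
# recording-level pipeline
# ---------------------------------------------------------------------------

def _eda_band_filters(eda_hp: np.ndarray, fs: float,
                      bands: SpectralBandsEDA) -> dict[str, np.ndarray]:
    """Band-limit the whole high-passed EDA signal once per band.

    Filtering the full signal (rather than each 10 s window) keeps the
    0.02 Hz band edge well-conditioned and avoids per-window transients.
    """
    return {
        "LF": pp._butter_zero_phase(eda_hp, fs, "band", bands.lf),
        "HF": pp._butter_zero_phase(eda_hp, fs, "band", bands.hf),
        "VHF": pp._butter_zero_phase(eda_hp, fs, "high", bands.vhf_low),
    }


def extract_features_for_recording(
    rec: MultichannelRecording,
    annotations: pd.DataFrame,
    config: FeatureConfig | None = None,
) -> pd.DataFrame:
    """Full per-recording pipeline: one row per (event, window), 80 columns.

    Channel conditioning happens once over the whole recording (z-score,
    ECG baseline removal + QRS detection, EDA high-pass + band splitting,
    RSP band-pass + breath segmentation, EMG decimation); windows then
    index into the detected fiducials and conditioned signals.
    """
    config = config or FeatureConfig()
    fs = rec.fs
    z = {c: pp.zscore(rec.channels[c]) for c in rec.channels}

    ecg = pp.ecg_remove_baseline(z["ecg"], fs)
    try:
        rr = pp.pan_tompkins(ecg, fs)
    except ValueError:
        rr = pp.RRSeries(np.empty(0), np.empty(0), np.empty(0))

    eda_hp = pp.eda_highpass(z["eda"], fs)
    eda_bands = _eda_band_filters(eda_hp, fs, config.eda_bands)
    rsp_f = pp.rsp_bandpass(z["rsp"], fs)
    breaths = pp.detect_breaths(rsp_f, fs, config.exhale_frac)
    emg32 = pp.emg_downsample(z["emg"], fs)
    fs32 = 32.0
    temp = z["temp"]

    rows = []
    for seg in extract_events(rec, annotations):
        bounds = (seg.start_s, seg.end_s)
        for w_idx, (w0, w1) in enumerate(make_windows(seg.duration,
                                                      config.window)):
            window = (seg.start_s + w0, seg.start_s + w1)
            feats: dict[str, float] = {}
            feats.update(ecg_time_features(rr, window))
            feats.update(ecg_freq_features(rr, window, bounds,
                                           config.ecg_bands))
            feats.update(rsp_features(breaths, window))
            feats.update(temp_features(temp, fs, window))
            i0, i1 = int(round(window[0] * fs32)), int(round(window[1] * fs32))
            feats.update(emg_wavelet_features(emg32[i0:i1], fs32))
            j0, j1 = int(round(window[0] * fs)), int(round(window[1] * fs))
            band_wins = {b: s[j0:j1] for b, s in eda_bands.items()}
            feats.update(eda_features(eda_hp[j0:j1], band_wins, fs, config))
            row = {
                "participant_id": rec.participant_id,
                "condition": rec.condition,
                "event_id": seg.event_id,
                "window_index": w_idx,
            }
            row.update({n: feats[n] for n in FEATURE_NAMES})
            rows.append(row)
    return pd.DataFrame(rows, columns=META_COLUMNS + FEATURE_NAMES)


def extract_feature_matrix(
    manifest: pd.DataFrame,
    config: FeatureConfig | None = None,
) -> pd.DataFrame:
    """Extract the cohort feature matrix from a manifest table.

    One row per (participant, event, window); participants contributing no
    valid window are excluded with a logged warning.
    """
    from .segmentation import load_annotations, load_recording

    config = config or FeatureConfig()
    frames = []
    for row in manifest.itertuples(index=False):
        rec = load_recording(row.recording_path,
                             participant_id=row.participant_id,
                             condition=row.condition)
        annotations = load_annotations(row.annotation_path)
        df = extract_features_for_recording(rec, annotations, config)
        if len(df) == 0:
            log.warning("participant %s excluded: no valid windows",
                        row.participant_id)
            continue
        frames.append(df)
    if not frames:
        return pd.DataFrame(columns=META_COLUMNS + FEATURE_NAMES)
    return pd.concat(frames, ignore_index=True)


def extract_feature_matrix_from_cohort(
    cohort: list,
    config: FeatureConfig | None = None,
) -> pd.DataFrame:
    """In-memory variant of :func:`extract_feature_matrix` for simulated
    cohorts (list of (recording, ground_truth, annotations) triples)."""
    frames = []
    for rec, _truth, annotations in cohort:
        df = extract_features_for_recording(rec, annotations, config)
        if len(df) == 0:
            log.warning("participant %s excluded: no valid windows",
                        rec.participant_id)
            continue
        frames.append(df)
    if not frames:
        return pd.DataFrame(columns=META_COLUMNS + FEATURE_NAMES)
    return pd.concat(frames, ignore_index=True)
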