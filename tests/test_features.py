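"""Windowing and the 80-feature inventory."""

import numpy as np
import pandas as pd
import pytest

import physio
from physio import preprocess as pp
from physio.features import (
    EDA_FEATURES,
    EMG_FEATURES,
    FEATURE_MODALITY,
    FEATURE_NAMES,
    FeatureConfig,
    SpectralBandsEDA,
    WindowSpec,
    _eda_band_filters,
    ecg_freq_features,
    ecg_time_features,
    eda_features,
    emg_wavelet_features,
    feature_subset,
    make_windows,
    rsp_features,
    temp_features,
)
from physio.preprocess import BreathCycleSeries, RRSeries


class TestInventory:
    def test_counts_per_modality(self):
        counts = pd.Series(list(FEATURE_MODALITY.values())).value_counts()
        assert counts["ECG"] == 31
        assert counts["RSP"] == 12
        assert counts["TEMP"] == 8
        assert counts["EDA"] == 12
        assert counts["EMG"] == 17
        assert len(FEATURE_NAMES) == 80

    def test_ablation_subsets(self):
        assert len(feature_subset(("EMG",))) == 63
        assert len(feature_subset(("EMG", "EDA"))) == 51

    def test_reported_feature_names_present(self):
        required = [
            "bpm", "R std", "RR mean", "pwr TP", "psd TP", "psd VLF",
            "pwr VLF", "R mad", "val mean", "Diffprd std", "HF time sam",
            "HF frq sam", "HF frq pwr", "Total Eng", "5-6 level (7) Eng%",
            "temp mean", "temp Diff std",
        ]
        for name in required:
            assert name in FEATURE_NAMES


class TestWindows:
    @pytest.mark.parametrize("duration, n", [(50.0, 5), (9.9, 0), (25.0, 2),
                                             (10.0, 1), (0.0, 0)])
    def test_window_counts(self, duration, n):
        assert len(make_windows(duration)) == n

    def test_windows_are_consecutive_and_half_open(self):
        wins = make_windows(25.0)
        assert wins == [(0.0, 10.0), (10.0, 20.0)]

    def test_invalid_spec_rejected(self):
        with pytest.raises(ValueError):
            WindowSpec(width=0.0)


def _rr_from_times(times, amps=None):
    times = np.asarray(times, float)
    amps = np.ones_like(times) if amps is None else np.asarray(amps, float)
    return RRSeries(times, amps, np.diff(times))


class TestEcgTime:
    def test_constant_rr(self):
        rr = _rr_from_times(np.arange(0.5, 9.5, 1.0))
        out = ecg_time_features(rr, (0.0, 10.0))
        assert out["RR mean"] == pytest.approx(1.0)
        assert out["RR std"] == pytest.approx(0.0)
        assert out["bpm"] == pytest.approx(60.0)
        assert out["RMSSD"] == pytest.approx(0.0)

    def test_two_interval_hand_arithmetic(self):
        rr = _rr_from_times([0.5, 1.3, 2.3])  # RR = [0.8, 1.0]
        out = ecg_time_features(rr, (0.0, 10.0))
        assert out["bpm"] == pytest.approx((75.0 + 60.0) / 2)
        assert out["RR mean"] == pytest.approx(0.9)

    def test_bpm_exceeds_rate_of_mean_rr_under_variability(self):
        rng = np.random.default_rng(0)
        times = np.cumsum(0.8 + 0.1 * rng.standard_normal(12))
        out = ecg_time_features(_rr_from_times(times), (0.0, 20.0))
        assert out["bpm"] >= 60.0 / out["RR mean"]

    def test_too_few_beats_flags_missing(self):
        out = ecg_time_features(_rr_from_times([0.5, 1.5]), (0.0, 10.0))
        assert np.isnan(out["RR mean"]) and np.isnan(out["bpm"])

    def test_r_amplitude_statistics(self):
        rr = _rr_from_times([1.0, 2.0, 3.0, 4.0], amps=[1.0, 2.0, 3.0, 4.0])
        out = ecg_time_features(rr, (0.0, 10.0))
        assert out["R mean"] == pytest.approx(2.5)
        assert out["Rdiff mean"] == pytest.approx(1.0)
        assert out["Rdiff std"] == pytest.approx(0.0)


class TestEcgFreq:
    def _tachogram(self, modulation_hz=None, duration=60.0):
        # beats with RR modulated (or not) around 0.8 s
        times = [0.0]
        while times[-1] < duration:
            rr = 0.8
            if modulation_hz is not None:
                rr += 0.05 * np.sin(2 * np.pi * modulation_hz * times[-1])
            times.append(times[-1] + rr)
        return _rr_from_times(times)

    def test_constant_rr_gives_zero_power(self):
        rr = self._tachogram(None)
        out = ecg_freq_features(rr, (20.0, 30.0), (0.0, 60.0))
        assert out["pwr TP"] == pytest.approx(0.0, abs=1e-12)

    def test_lf_modulation_concentrates_power_in_lf(self):
        rr = self._tachogram(0.10)
        out = ecg_freq_features(rr, (20.0, 30.0), (0.0, 60.0))
        assert out["pwr LF"] / out["pwr TP"] >= 0.90
        assert out["peak-freq LF"] == pytest.approx(0.10, abs=0.04)

    def test_total_power_is_sum_of_bands(self):
        rr = self._tachogram(0.23)
        out = ecg_freq_features(rr, (20.0, 30.0), (0.0, 60.0))
        assert out["pwr TP"] == out["pwr VLF"] + out["pwr LF"] + out["pwr HF"]

    def test_insufficient_coverage_gives_missing(self):
        rr = _rr_from_times(np.arange(0.0, 8.0, 0.8))
        out = ecg_freq_features(rr, (0.0, 10.0), (0.0, 10.0))
        assert np.isnan(out["pwr TP"])


class TestRsp:
    def _breaths(self, onsets, depths, periods):
        onsets = np.asarray(onsets, float)
        return BreathCycleSeries(onsets, np.asarray(depths, float),
                                 np.asarray(periods, float),
                                 0.5 * np.asarray(periods, float))

    def test_identical_cycles(self):
        b = self._breaths([0.0, 4.0, 8.0], [2.0] * 3, [4.0] * 3)
        out = rsp_features(b, (0.0, 12.0))
        assert out["val mean"] == pytest.approx(2.0)
        assert out["prd mean"] == pytest.approx(4.0)
        assert out["Diffprd std"] == pytest.approx(0.0)
        assert out["breath rate"] == pytest.approx(15.0)
        assert out["duty ratio"] == pytest.approx(0.5)

    def test_period_progression_hand_arithmetic(self):
        b = self._breaths([0.0, 3.0, 7.0], [1.0] * 3, [3.0, 4.0, 5.0])
        out = rsp_features(b, (0.0, 12.0))
        assert out["prd mean"] == pytest.approx(4.0)
        assert out["Diffprd mean"] == pytest.approx(1.0)
        assert out["Diffprd std"] == pytest.approx(0.0)

    def test_single_cycle_missing(self):
        b = self._breaths([1.0], [2.0], [4.0])
        out = rsp_features(b, (0.0, 10.0))
        assert all(np.isnan(v) for v in out.values())


class TestTemp:
    def test_constant_window(self):
        out = temp_features(np.full(20_000, 0.7), 1000.0, (0.0, 10.0))
        assert out["temp mean"] == pytest.approx(0.7)
        assert out["temp std"] == pytest.approx(0.0)
        assert out["temp Diff std"] == pytest.approx(0.0)

    def test_linear_ramp_first_differences(self):
        x = 0.001 * np.arange(20_000)
        out = temp_features(x, 1000.0, (0.0, 10.0))
        assert out["temp Diff mean"] == pytest.approx(0.001)
        assert out["temp Diff std"] == pytest.approx(0.0, abs=1e-12)

    def test_matches_direct_recomputation(self):
        rng = np.random.default_rng(3)
        x = np.cumsum(rng.standard_normal(30_000)) * 1e-3
        out = temp_features(x, 1000.0, (10.0, 20.0))
        w = x[10_000:20_000]
        assert out["temp mean"] == pytest.approx(w.mean())
        assert out["temp std"] == pytest.approx(w.std())
        assert out["temp min"] == pytest.approx(w.min())
        assert out["temp Diff mad"] == pytest.approx(
            float(np.median(np.abs(np.diff(w) - np.median(np.diff(w))))))


class TestEmgWavelet:
    def test_zero_window(self):
        out = emg_wavelet_features(np.zeros(320))
        assert out["Total Eng"] == 0.0
        assert np.isnan(out["d1 Eng%"])

    def test_energy_proportions_sum_to_one(self):
        rng = np.random.default_rng(1)
        out = emg_wavelet_features(rng.standard_normal(320))
        total_pct = sum(out[f"{b} Eng%"]
                        for b in ("d1", "d2", "d3", "d4", "d5", "d6", "a6"))
        assert total_pct == pytest.approx(1.0, abs=1e-9)

    def test_energy_conservation(self):
        rng = np.random.default_rng(2)
        x = rng.standard_normal(320)
        out = emg_wavelet_features(x)
        assert out["Total Eng"] == pytest.approx(float(np.sum(x ** 2)),
                                                 rel=1e-9)

    def test_8hz_tone_lands_in_d1(self):
        t = np.arange(320) / 32.0
        out = emg_wavelet_features(np.sin(2 * np.pi * 8.0 * t))
        bands = ("d1", "d2", "d3", "d4", "d5", "d6", "a6")
        assert max(bands, key=lambda b: out[f"{b} Eng%"]) == "d1"


class TestEda:
    def test_flat_window_all_zero(self):
        zeros = np.zeros(10_000)
        bands = {b: zeros for b in ("LF", "HF", "VHF")}
        out = eda_features(zeros, bands, 1000.0)
        assert all(v == 0.0 for v in out.values())

    def test_hf_tone_dominates_hf_band_power(self):
        fs = 1000.0
        t = np.arange(10_000) / fs
        x = np.sin(2 * np.pi * 0.7 * t)
        bands = _eda_band_filters(x, fs, SpectralBandsEDA())
        out = eda_features(x, bands, fs)
        assert out["HF frq pwr"] > out["LF frq pwr"]
        assert out["HF frq pwr"] > out["VHF frq pwr"]

    def test_scr_kernel_count_monotone_in_injected_events(self):
        from physio.synth import _scr_kernel
        fs = 1000.0
        kern = 0.5 * _scr_kernel(fs)
        counts = []
        for n_scr in (2, 5, 9):
            x = np.zeros(10_000)
            for i in range(n_scr):
                at = int(i * 10_000 / n_scr)
                seg = kern[: 10_000 - at]
                x[at:at + len(seg)] += seg
            bands = _eda_band_filters(x, fs, SpectralBandsEDA())
            out = eda_features(x, bands, fs)
            counts.append(out["HF time sam"] + out["LF time sam"])
        assert counts[0] <= counts[1] <= counts[2]
        assert counts[2] >= 9


class TestMatrix:
    def test_fully_annotated_cohort_window_count(self, profiles):
        play, _ = profiles
        rec, _ = physio.generate_recording(play, 120.0, seed=31)
        ann = pd.DataFrame([{"event_id": "16", "label": "full",
                             "start_s": 0.0, "end_s": 120.0}])
        df = physio.extract_features_for_recording(rec, ann)
        assert len(df) == 12  # 120 s fully annotated -> 12 windows
        assert list(df.columns[4:]) == list(FEATURE_NAMES)

    def test_matrix_shape_and_labels(self, small_matrix):
        assert set(small_matrix["condition"]) == {"GamePlay", "GameWatch"}
        assert small_matrix.shape[1] == 4 + 80
        # ablation column bookkeeping on the real matrix
        assert len([c for c in small_matrix.columns
                    if FEATURE_MODALITY.get(c) not in (None, "EMG")]) == 63

    def test_offset_invariance_of_ecg_features(self, profiles):
        # adding a constant to the raw ECG is absorbed by z-scoring
        play, _ = profiles
        rec, _ = physio.generate_recording(play, 120.0, seed=41)
        ann = physio.synth.default_event_schedule(120.0)
        base = physio.extract_features_for_recording(rec, ann)
        rec.channels["ecg"] = rec.channels["ecg"] + 5.0
        shifted = physio.extract_features_for_recording(rec, ann)
        ecg_cols = [f for f in FEATURE_NAMES if FEATURE_MODALITY[f] == "ECG"]
        pd.testing.assert_frame_equal(base[ecg_cols], shifted[ecg_cols],
                                      rtol=1e-6, atol=1e-9)

    def test_scr_rate_monotonically_drives_hf_time_sam(self, profiles):
        import dataclasses
        from scipy.stats import spearmanr
        play, _ = profiles
        rates = [2.0, 6.0, 12.0, 20.0, 30.0]
        means = []
        for rate in rates:
            vals = []
            for seed in range(3):
                prof = dataclasses.replace(play, scr_rate=rate)
                rec, _ = physio.generate_recording(prof, 120.0, seed=seed)
                ann = physio.synth.default_event_schedule(120.0)
                df = physio.extract_features_for_recording(rec, ann)
                vals.append(df["HF time sam"].mean())
            means.append(np.mean(vals))
        rho, _ = spearmanr(rates, means)
        assert rho > 0.9
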