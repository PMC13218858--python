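"""Synthetic multimodal cohort generator with known ground truth.

The generator stands in for non-shareable participant recordings.  It
emulates the statistical structure the analysis assumes: two conditions
(active GamePlay vs. passive GameWatch), five 1000 Hz channels per
participant, and annotated emotional-challenge events late in each
recording.  Condition profiles carry the group-level physiology — heart
rate and its spreads, respiratory depth/period, phasic electrodermal event
rate and amplitude, EMG energy and spectral split, and temperature offset —
so that features extracted downstream differ between conditions in the
directions observed in the study this pipeline is built for (higher heart
rate, lower beat-to-beat variability, shallower/less stable breathing,
more phasic EDA, warmer periphery during active play).

Every recording is reproducible from a single integer seed, which is split
into independent per-channel substreams; ``GroundTruth`` records the true
beat times, phasic-event times and breath boundaries so detectors can be
scored exactly.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.ndimage import uniform_filter1d
from scipy.signal import butter, lfilter, sosfiltfilt

from .segmentation import (
    CHANNELS,
    DEFAULT_FS,
    MultichannelRecording,
    write_annotations,
    write_recording,
)

#: fraction of each recording before the first emotional-challenge event
BASELINE_FRACTION = 0.25
#: canonical emotional-challenge beats of the final quest (event ids 16-20)
EVENT_LABELS = [
    ("16", "maxson_order"),
    ("17", "quinlan_confirmation"),
    ("18", "haylen_search"),
    ("19", "danse_confrontation"),
    ("20", "maxson_confrontation"),
]
#: SCR kernel time constants (s): canonical bi-exponential rise/decay
SCR_RISE_S = 0.75
SCR_DECAY_S = 2.0
#: R-peak amplitude jitter is coupled to RR jitter (shared autonomic tone)
R_AMP_JITTER_PER_RR_SD = 2.5
#: reference (non-event) respiratory depth, amplitude units
RESP_BASELINE_DEPTH = 1.5
#: per-breath relative depth jitter
RESP_DEPTH_JITTER = 0.10
#: temperature fluctuation correlation time (s)
TEMP_OU_TAU = 10.0


@dataclass
class ConditionProfile:
    """Generator parameters for one experimental condition."""

    label: str
    hr_mean: float            # beats/min, group mean heart rate
    hr_between_sd: float      # beats/min, between-participant spread
    rr_within_sd: float       # s, beat-to-beat RR jitter
    resp_depth_mean: float    # amplitude units, event-period breathing depth
    resp_period_mean: float   # s, mean breath period
    resp_period_jitter: float # s, breath-to-breath period jitter
    scr_rate: float           # phasic EDA events per minute
    scr_amp_mean: float       # microsiemens-like units
    emg_total_energy_scale: float  # unitless amplitude multiplier
    emg_fine_fraction: float  # power fraction above 1 Hz (32 Hz-referenced)
    temp_offset: float        # z-units, event-period temperature elevation
    temp_drift_sd: float      # z-units/s, temperature fluctuation drive

    def validate(self) -> None:
        if self.hr_mean <= 0:
            raise ValueError("invalid profile: hr_mean must be > 0")
        if self.rr_within_sd < 0:
            raise ValueError("invalid profile: rr_within_sd must be >= 0")
        if self.resp_period_mean <= 0:
            raise ValueError("invalid profile: resp_period_mean must be > 0")
        if self.scr_rate < 0:
            raise ValueError("invalid profile: scr_rate must be >= 0")
        if not (0.0 < self.emg_fine_fraction < 1.0):
            raise ValueError(
                "invalid profile: emg_fine_fraction must be in (0, 1)"
            )

    @classmethod
    def from_json(cls, path) -> "ConditionProfile":
        with open(path) as fh:
            return cls(**json.load(fh))

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(dataclasses.asdict(self), fh, indent=2)


@dataclass
class GroundTruth:
    """True event times underlying one synthetic recording."""

    r_peak_times: np.ndarray      # s
    scr_event_times: np.ndarray   # s, SCR onsets
    breath_boundaries: np.ndarray # s, inspiration onsets
    channel_seeds: dict[str, int]
    heart_rate: float             # beats/min realized for this participant


def default_profiles() -> tuple[ConditionProfile, ConditionProfile]:
    """The shipped GamePlay/GameWatch profiles (editable JSON defaults)."""
    pkg = resources.files("physio") / "profiles"
    play = ConditionProfile(**json.loads((pkg / "gameplay.json").read_text()))
    watch = ConditionProfile(**json.loads((pkg / "gamewatch.json").read_text()))
    return play, watch


def default_event_schedule(
    duration: float, rng: np.random.Generator | None = None
) -> pd.DataFrame:
    """Annotation table for one recording: five sequential events.

    The first ``BASELINE_FRACTION`` of the recording is unannotated
    (pre-event narrative build-up); the remainder is split into the five
    emotional-challenge events with short gaps, so the union covers well
    over 60% of the recording.  With an RNG, event boundaries are jittered
    by a few percent to emulate per-participant pacing.
    """
    start = BASELINE_FRACTION * duration
    gap = min(1.0, 0.004 * duration)
    n_ev = len(EVENT_LABELS)
    usable = duration - start - gap * (n_ev - 1)
    lengths = np.full(n_ev, usable / n_ev)
    if rng is not None:
        w = rng.uniform(0.85, 1.15, size=n_ev)
        lengths = usable * w / w.sum()
    rows = []
    t = start
    for (event_id, label), length in zip(EVENT_LABELS, lengths):
        rows.append(
            {"event_id": event_id, "label": label,
             "start_s": round(t, 3), "end_s": round(t + length, 3)}
        )
        t += length + gap
    df = pd.DataFrame(rows)
    df.loc[df.index[-1], "end_s"] = min(df["end_s"].iloc[-1], duration)
    return df


def _event_modulation(n: int, fs: float, annotations: pd.DataFrame,
                      ramp_s: float = 5.0) -> np.ndarray:
    """0/1 event indicator smoothed with a ``ramp_s`` moving average."""
    m = np.zeros(n)
    for row in annotations.itertuples(index=False):
        i0 = int(round(row.start_s * fs))
        i1 = int(round(row.end_s * fs))
        m[i0:i1] = 1.0
    width = max(1, int(round(ramp_s * fs)))
    return uniform_filter1d(m, size=width, mode="nearest")


# ---------------------------------------------------------------------------
# per-channel synthesis
# ---------------------------------------------------------------------------

def _ecg_template(fs: float) -> tuple[np.ndarray, int]:
    """P-QRS-T morphology as a sum of Gaussians, R amplitude 1.0 at center."""
    half = int(round(0.40 * fs))
    t = np.arange(-half, half + 1) / fs
    waves = [  # (amplitude, center s, width s)
        (0.12, -0.180, 0.028),   # P
        (-0.12, -0.022, 0.008),  # Q
        (1.00, 0.0, 0.012),      # R
        (-0.18, 0.025, 0.009),   # S
        (0.30, 0.270, 0.060),    # T
    ]
    tpl = np.zeros_like(t)
    for a, mu, sig in waves:
        tpl += a * np.exp(-0.5 * ((t - mu) / sig) ** 2)
    # force the exact center sample to be the template maximum
    tpl[half] = max(tpl[half], tpl.max())
    return tpl, half


def _place_templates(n: int, fs: float, times: np.ndarray,
                     amps: np.ndarray, tpl: np.ndarray, half: int
                     ) -> np.ndarray:
    out = np.zeros(n)
    idx = np.round(times * fs).astype(int)
    for i, a in zip(idx, amps):
        lo, hi = i - half, i + half + 1
        tlo = max(0, -lo)
        thi = len(tpl) - max(0, hi - n)
        out[max(lo, 0):min(hi, n)] += a * tpl[tlo:thi]
    return out


def _gen_ecg(profile: ConditionProfile, duration: float, n: int, fs: float,
             rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray, float]:
    hr = float(np.clip(rng.normal(profile.hr_mean, profile.hr_between_sd),
                       40.0, 160.0))
    mean_rr = 60.0 / hr
    # integrate-and-fire beat times
    max_beats = int(duration / mean_rr * 2) + 8
    rr = mean_rr + profile.rr_within_sd * rng.standard_normal(max_beats)
    np.clip(rr, 0.33 * mean_rr, 3.0 * mean_rr, out=rr)
    t0 = rng.uniform(0.0, 1.0) * rr[0]
    beats = t0 + np.concatenate(([0.0], np.cumsum(rr[1:])))
    beats = beats[beats < duration - 1.0 / fs]
    amp_sd = R_AMP_JITTER_PER_RR_SD * profile.rr_within_sd
    amps = 1.0 + amp_sd * rng.standard_normal(len(beats))
    tpl, half = _ecg_template(fs)
    x = _place_templates(n, fs, beats, amps, tpl, half)
    # baseline wander (respiratory-band + very slow) and sensor noise
    t = np.arange(n) / fs
    x += 0.20 * np.sin(2 * np.pi * 0.33 * t + rng.uniform(0, 2 * np.pi))
    x += 0.10 * np.sin(2 * np.pi * 0.05 * t + rng.uniform(0, 2 * np.pi))
    x += 0.02 * rng.standard_normal(n)
    return x, beats, hr


def _scr_kernel(fs: float) -> np.ndarray:
    t = np.arange(0, int(8.0 * fs)) / fs
    k = np.exp(-t / SCR_DECAY_S) - np.exp(-t / SCR_RISE_S)
    return k / k.max()


def _gen_eda(profile: ConditionProfile, duration: float, n: int, fs: float,
             rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    # tonic level: slow Ornstein-Uhlenbeck drift around a baseline level
    dt = 1.0 / fs
    tau = 30.0
    drive = 0.25 * np.sqrt(2 * dt / tau)
    steps = drive * rng.standard_normal(n)
    decay = 1.0 - dt / tau
    ou = lfilter([1.0], [1.0, -decay], steps)  # AR(1) recursion
    # tonic skin conductance is very slow; strip the AR tail above 0.05 Hz
    # so the phasic kernels are the only fast structure in the channel
    sos = butter(2, 0.05, btype="low", fs=fs, output="sos")
    ou = sosfiltfilt(sos, ou)
    x = 5.0 + ou / max(np.std(ou), 1e-12) * 1.0
    # phasic SCRs at Poisson times
    n_scr = rng.poisson(profile.scr_rate / 60.0 * duration)
    times = np.sort(rng.uniform(0.0, max(duration - 1.0, 0.0), size=n_scr))
    if n_scr > 0:
        amps = profile.scr_amp_mean * np.exp(
            rng.normal(-0.045, 0.3, size=n_scr))
        kern = _scr_kernel(fs)
        idx = np.round(times * fs).astype(int)
        for i, a in zip(idx, amps):
            hi = min(i + len(kern), n)
            x[i:hi] += a * kern[: hi - i]
    x += 0.01 * rng.standard_normal(n)
    return x, times


def _gen_rsp(profile: ConditionProfile, duration: float, n: int, fs: float,
             rng: np.random.Generator, modulation: np.ndarray
             ) -> tuple[np.ndarray, np.ndarray]:
    max_breaths = int(duration / max(profile.resp_period_mean, 1.0) * 3) + 8
    periods = profile.resp_period_mean + \
        profile.resp_period_jitter * rng.standard_normal(max_breaths)
    np.clip(periods, 1.2, 4.0 * profile.resp_period_mean, out=periods)
    t0 = rng.uniform(0.0, 1.0) * periods[0]
    onsets = t0 + np.concatenate(([0.0], np.cumsum(periods[:-1])))
    keep = onsets < duration
    onsets, periods = onsets[keep], periods[keep]
    x = np.zeros(n)
    depth_env = RESP_BASELINE_DEPTH + \
        (profile.resp_depth_mean - RESP_BASELINE_DEPTH) * modulation
    for onset, period in zip(onsets, periods):
        i0 = int(round(onset * fs))
        i1 = min(int(round((onset + period) * fs)), n)
        if i1 <= i0:
            continue
        mid = min((i0 + i1) // 2, n - 1)
        depth = depth_env[mid] * (1 + RESP_DEPTH_JITTER * rng.standard_normal())
        phase = (np.arange(i0, i1) / fs - onset) / period
        x[i0:i1] = -(depth / 2.0) * np.cos(2 * np.pi * phase)
    x += 0.01 * rng.standard_normal(n)
    return x, onsets


def _gen_emg(profile: ConditionProfile, n: int, fs: float,
             rng: np.random.Generator) -> np.ndarray:
    """Noise shaped below the 16 Hz band kept by the 32 Hz downsampling.

    Power splits between a coarse (<1 Hz) and a fine (1-16 Hz) component
    per ``emg_fine_fraction``; total amplitude scales linearly with
    ``emg_total_energy_scale`` so energy is quadratic in the scale.
    """
    white1 = rng.standard_normal(n)
    white2 = rng.standard_normal(n)
    sos_lo = butter(2, 1.0, btype="low", fs=fs, output="sos")
    sos_hi = butter(2, [1.0, 16.0], btype="band", fs=fs, output="sos")
    lo = sosfiltfilt(sos_lo, white1)
    hi = sosfiltfilt(sos_hi, white2)
    lo /= max(np.std(lo), 1e-12)
    hi /= max(np.std(hi), 1e-12)
    f = profile.emg_fine_fraction
    x = np.sqrt(1.0 - f) * lo + np.sqrt(f) * hi
    return profile.emg_total_energy_scale * x


def _gen_temp(profile: ConditionProfile, n: int, fs: float,
              rng: np.random.Generator, modulation: np.ndarray) -> np.ndarray:
    dt = 1.0 / fs
    decay = 1.0 - dt / TEMP_OU_TAU
    drive = profile.temp_drift_sd * np.sqrt(dt)
    steps = drive * rng.standard_normal(n)
    ou = lfilter([1.0], [1.0, -decay], steps)  # AR(1) recursion
    # sensor noise floor varies between participants (placement, gain)
    noise_sd = 0.002 * np.exp(0.3 * rng.standard_normal())
    return profile.temp_offset * modulation + ou + \
        noise_sd * rng.standard_normal(n)


# ---------------------------------------------------------------------------
# public API
# ---------------------------------------------------------------------------

def generate_recording(
    profile: ConditionProfile,
    duration: float,
    seed: int,
    participant_id: str = "p00",
    events: pd.DataFrame | None = None,
    fs: float = DEFAULT_FS,
) -> tuple[MultichannelRecording, GroundTruth]:
    """Synthesize one five-channel recording plus its ground truth.

    `events` (an annotation table) drives the within-recording structure:
    respiratory depth and skin temperature shift from their pre-event
    baseline to the profile's event-period values.  When omitted, the
    canonical event schedule for `duration` is used.
    """
    if duration < 60:
        raise ValueError("duration must be >= 60 s")
    profile.validate()
    if events is None:
        events = default_event_schedule(duration)
    n = int(round(duration * fs))
    ss = np.random.SeedSequence(seed)
    kids = ss.spawn(len(CHANNELS))
    seeds = {c: int(k.generate_state(1)[0]) % (2**31)
             for c, k in zip(CHANNELS, kids)}
    rngs = {c: np.random.default_rng(k) for c, k in zip(CHANNELS, kids)}
    modulation = _event_modulation(n, fs, events)

    ecg, beats, hr = _gen_ecg(profile, duration, n, fs, rngs["ecg"])
    eda, scr_times = _gen_eda(profile, duration, n, fs, rngs["eda"])
    rsp, breath_onsets = _gen_rsp(profile, duration, n, fs, rngs["rsp"],
                                  modulation)
    emg = _gen_emg(profile, n, fs, rngs["emg"])
    temp = _gen_temp(profile, n, fs, rngs["temp"], modulation)

    channels = {"ecg": ecg, "eda": eda, "rsp": rsp, "emg": emg, "temp": temp}
    # round to the precision of the plain-text signal files so an on-disk
    # round trip reproduces the in-memory samples exactly
    channels = {c: np.round(v, 5) for c, v in channels.items()}
    rec = MultichannelRecording(
        participant_id=participant_id, condition=profile.label,
        fs=fs, channels=channels,
    )
    truth = GroundTruth(
        r_peak_times=beats, scr_event_times=scr_times,
        breath_boundaries=breath_onsets, channel_seeds=seeds, heart_rate=hr,
    )
    return rec, truth


def simulate_cohort(
    play_profile: ConditionProfile,
    watch_profile: ConditionProfile,
    n_per_group: int,
    duration: float,
    seed: int,
) -> list[tuple[MultichannelRecording, GroundTruth, pd.DataFrame]]:
    """In-memory cohort: one (recording, truth, annotations) per participant.

    Participants alternate GamePlay/GameWatch ids; every participant gets a
    seed derived from the cohort seed, so the whole cohort is reproducible.
    """
    if n_per_group < 2:
        raise ValueError("n_per_group must be >= 2")
    for p in (play_profile, watch_profile):
        p.validate()
    ss = np.random.SeedSequence(seed)
    out = []
    kids = ss.spawn(2 * n_per_group)
    i = 0
    for profile, tag in ((play_profile, "play"), (watch_profile, "watch")):
        for j in range(n_per_group):
            sched_seq, rec_seq = kids[i].spawn(2)
            i += 1
            pid = f"{tag}{j:02d}"
            annotations = default_event_schedule(
                duration, np.random.default_rng(sched_seq))
            rec_seed = int(rec_seq.generate_state(1)[0]) % (2**31)
            rec, truth = generate_recording(
                profile, duration, rec_seed, participant_id=pid,
                events=annotations,
            )
            out.append((rec, truth, annotations))
    return out


def generate_cohort(
    play_profile: ConditionProfile,
    watch_profile: ConditionProfile,
    n_per_group: int,
    duration: float,
    seed: int,
    out_dir,
) -> pd.DataFrame:
    """Write a cohort to `out_dir` and return the manifest table.

    One signal CSV and one annotation TSV per participant; the manifest has
    columns ``participant_id,condition,ending,recording_path,
    annotation_path`` with the narrative endings allocated 12:2-style
    (1/7 of each group executes, at least one, mirroring the skewed choice
    distribution the paradigm produces).
    """
    out_dir = Path(out_dir)
    try:
        out_dir.mkdir(parents=True, exist_ok=True)
    except OSError as exc:
        raise OSError(f"cannot create output directory {out_dir}: {exc}")
    cohort = simulate_cohort(play_profile, watch_profile, n_per_group,
                             duration, seed)
    n_execute = max(1, round(n_per_group * 2 / 14))
    rows = []
    for rec, _truth, annotations in cohort:
        rec_path = out_dir / f"{rec.participant_id}_signals.csv"
        ann_path = out_dir / f"{rec.participant_id}_events.tsv"
        try:
            write_recording(rec_path, rec)
            write_annotations(ann_path, annotations)
        except OSError as exc:
            raise OSError(f"failed writing {rec_path}: {exc}")
        idx = int(rec.participant_id[-2:])
        rows.append({
            "participant_id": rec.participant_id,
            "condition": rec.condition,
            "ending": "execute" if idx < n_execute else "spare",
            "recording_path": str(rec_path),
            "annotation_path": str(ann_path),
        })
    manifest = pd.DataFrame(rows)
    manifest.to_csv(out_dir / "manifest.csv", index=False)
    return manifest
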