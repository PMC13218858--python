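"""Recording/annotation I/O and event-based signal segmentation.

Recordings hold five synchronized peripheral channels (ECG, EDA, RSP, EMG,
skin temperature) sampled at 1000 Hz.  Analysis is event-based: only the
annotated emotional-challenge intervals of each recording are cut out and
passed downstream, so that feature windows never mix event and non-event
physiology.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

CHANNELS = ("ecg", "eda", "rsp", "emg", "temp")
DEFAULT_FS = 1000.0


@dataclass
class MultichannelRecording:
    """Five synchronized signal channels plus participant metadata."""

    participant_id: str
    condition: str
    fs: float
    channels: dict[str, np.ndarray]

    def __post_init__(self) -> None:
        if self.fs <= 0:
            raise ValueError("fs must be positive")
        missing = [c for c in CHANNELS if c not in self.channels]
        if missing:
            raise ValueError(f"missing channel: {missing[0]}")
        lengths = {len(v) for v in self.channels.values()}
        if len(lengths) != 1:
            raise ValueError("all channels must have equal length")

    @property
    def n_samples(self) -> int:
        return len(self.channels["ecg"])

    @property
    def duration(self) -> float:
        return self.n_samples / self.fs


@dataclass
class EventSegment:
    """One annotated emotional-challenge interval cut out of a recording.

    Sample indices follow the half-open convention
    ``[round(start_s*fs), round(end_s*fs))`` so adjacent events partition
    the signal with no shared sample.
    """

    participant_id: str
    condition: str
    event_id: str
    label: str
    start_s: float
    end_s: float
    fs: float
    channels: dict[str, np.ndarray] = field(repr=False)

    @property
    def duration(self) -> float:
        return self.end_s - self.start_s

    @property
    def n_samples(self) -> int:
        return len(self.channels["ecg"])


def load_recording(
    path,
    participant_id: str = "",
    condition: str = "",
    expected_fs: float = DEFAULT_FS,
) -> MultichannelRecording:
    """Parse a plain-text signal file into a :class:`MultichannelRecording`.

    The file is CSV with header ``time_s,ecg,eda,rsp,emg,temp``.  The
    sampling rate is inferred from the time column and validated against
    `expected_fs` within 0.1%.
    """
    df = pd.read_csv(path)
    for col in ("time_s",) + CHANNELS:
        if col not in df.columns:
            raise ValueError(f"missing channel: {col}" if col != "time_s"
                             else "missing column: time_s")
    if df.isna().any().any():
        row = int(df.isna().any(axis=1).idxmax())
        raise ValueError(f"ragged or non-numeric row {row} in {path}")
    t = df["time_s"].to_numpy(float)
    if len(t) < 2:
        raise ValueError(f"recording too short in {path}")
    dt = np.diff(t)
    if np.any(dt <= 0):
        row = int(np.argmax(dt <= 0)) + 1
        raise ValueError(f"non-monotone time at row {row} in {path}")
    fs = 1.0 / np.median(dt)
    if abs(fs - expected_fs) > 1e-3 * expected_fs:
        raise ValueError(
            f"sampling rate {fs:.2f} Hz differs from expected {expected_fs} Hz"
        )
    channels = {c: df[c].to_numpy(float) for c in CHANNELS}
    return MultichannelRecording(
        participant_id=participant_id, condition=condition,
        fs=expected_fs, channels=channels,
    )


def load_annotations(path) -> pd.DataFrame:
    """Read an annotation TSV (``event_id  label  start_s  end_s``)."""
    df = pd.read_csv(path, sep="\t")
    required = ["event_id", "label", "start_s", "end_s"]
    for col in required:
        if col not in df.columns:
            raise ValueError(f"annotation file missing column: {col}")
    return df[required]


def extract_events(
    rec: MultichannelRecording, annotations: pd.DataFrame
) -> list[EventSegment]:
    """Cut one :class:`EventSegment` per annotation row, order preserved.

    Intervals must lie within the recording and must not overlap; both
    violations raise with the offending ``event_id``.  The slicing is
    deterministic and independent of channel contents.
    """
    segments: list[EventSegment] = []
    rows = list(annotations.itertuples(index=False))
    for row in rows:
        if not (0 <= row.start_s < row.end_s <= rec.duration + 1e-9):
            raise ValueError(
                f"event {row.event_id}: interval [{row.start_s}, {row.end_s}] "
                f"out of bounds for a {rec.duration:.3f} s recording"
            )
    ordered = sorted(rows, key=lambda r: r.start_s)
    for a, b in zip(ordered, ordered[1:]):
        if b.start_s < a.end_s - 1e-9:
            raise ValueError(
                f"overlapping events: {a.event_id} and {b.event_id}"
            )
    for row in rows:
        i0 = int(round(row.start_s * rec.fs))
        i1 = int(round(row.end_s * rec.fs))
        channels = {c: rec.channels[c][i0:i1] for c in CHANNELS}
        segments.append(
            EventSegment(
                participant_id=rec.participant_id,
                condition=rec.condition,
                event_id=str(row.event_id),
                label=str(row.label),
                start_s=float(row.start_s),
                end_s=float(row.end_s),
                fs=rec.fs,
                channels=channels,
            )
        )
    return segments


def write_recording(path, rec: MultichannelRecording) -> None:
    """Write a recording as CSV (``time_s,ecg,eda,rsp,emg,temp``)."""
    n = rec.n_samples
    t = np.arange(n) / rec.fs
    df = pd.DataFrame({"time_s": t, **{c: rec.channels[c] for c in CHANNELS}})
    df.to_csv(path, index=False, float_format="%.5f")


def write_annotations(path, annotations: pd.DataFrame) -> None:
    annotations.to_csv(path, sep="\t", index=False, float_format="%.3f")
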