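"""Recording I/O and sliding-window segmentation.

Recordings are multichannel acceleration series (g units) sampled at a known
rate, optionally carrying per-sample activity annotations. Classification
operates on *data frames*: fixed-width windows, typically 50% overlapping,
cut from the recording. Annotated transition intervals between activities
are propagated to frame labels so that supervised fitting can exclude them.
"""
from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "Recording",
    "FrameSet",
    "read_recording",
    "write_recording",
    "read_annotation_intervals",
    "expand_annotations",
    "segment_frames",
    "TRANSITION_LABEL",
    "UNKNOWN_LABEL",
]

TRANSITION_LABEL = "transition"
UNKNOWN_LABEL = "unknown"


@dataclass
class Recording:
    """Multichannel acceleration time series.

    channels : (n_channels, n_samples) array, g units, file column order.
    fs : sampling rate in Hz.
    annotations : optional (n_samples,) array of per-sample labels.
    """

    channels: np.ndarray
    fs: float
    annotations: np.ndarray | None = None
    subject_id: str | None = None

    def __post_init__(self) -> None:
        self.channels = np.atleast_2d(np.asarray(self.channels, dtype=float))
        if self.fs <= 0:
            raise ValueError("sampling rate must be positive")
        if self.annotations is not None:
            self.annotations = np.asarray(self.annotations, dtype=object)
            if self.annotations.shape[0] != self.n_samples:
                raise ValueError(
                    f"annotation length {self.annotations.shape[0]} != "
                    f"{self.n_samples} samples"
                )

    @property
    def n_channels(self) -> int:
        return self.channels.shape[0]

    @property
    def n_samples(self) -> int:
        return self.channels.shape[1]

    @property
    def duration(self) -> float:
        """Recording span in seconds."""
        return self.n_samples / self.fs


@dataclass
class FrameSet:
    """Frames cut from one recording: (n_frames, n_channels, width) blocks."""

    frames: np.ndarray
    width: int
    step: int
    starts: np.ndarray
    frame_labels: list[str] | None = None
    fs: float | None = None

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=float)
        if self.frame_labels is not None and len(self.frame_labels) != len(self):
            raise ValueError("one label per frame required")

    def __len__(self) -> int:
        return self.frames.shape[0]


def read_recording(
    path,
    fs: float,
    annotation_path=None,
    subject_id: str | None = None,
    vocabulary=None,
) -> Recording:
    """Read a CSV recording (one row per sample, one column per axis).

    A header row of channel names is detected automatically. Ragged or
    non-numeric rows and empty files raise ``ValueError``.
    """
    try:
        with open(path) as fh:
            first = fh.readline()
        if not first.strip():
            raise ValueError(f"{path}: empty recording file")
        has_header = False
        for tok in first.strip().split(","):
            try:
                float(tok)
            except ValueError:
                has_header = True
                break
        df = pd.read_csv(
            path, header=0 if has_header else None, float_precision="round_trip"
        )
    except pd.errors.EmptyDataError as exc:
        raise ValueError(f"{path}: empty recording file") from exc
    except pd.errors.ParserError as exc:
        raise ValueError(f"{path}: ragged rows, cannot parse") from exc
    if df.empty:
        raise ValueError(f"{path}: no samples")
    values = df.to_numpy()
    if not np.issubdtype(values.dtype, np.number) or np.isnan(
        values.astype(float)
    ).any():
        raise ValueError(f"{path}: non-numeric or ragged rows")
    channels = values.astype(float).T
    annotations = None
    if annotation_path is not None:
        intervals = read_annotation_intervals(annotation_path, vocabulary)
        annotations = expand_annotations(intervals, channels.shape[1])
    return Recording(channels, fs, annotations, subject_id)


def write_recording(rec: Recording, path, annotation_path=None) -> None:
    """Write a recording as CSV; floats round-trip bit-exactly."""
    cols = {f"ch{i + 1}": rec.channels[i] for i in range(rec.n_channels)}
    # 17 significant digits guarantee float64 round-trips bit-exactly
    pd.DataFrame(cols).to_csv(path, index=False, float_format="%.17g")
    if annotation_path is not None:
        if rec.annotations is None:
            raise ValueError("recording has no annotations to write")
        rows = []
        labels = rec.annotations
        start = 0
        for i in range(1, len(labels) + 1):
            if i == len(labels) or labels[i] != labels[start]:
                rows.append((start, i, labels[start]))
                start = i
        pd.DataFrame(rows, columns=["start_sample", "end_sample", "label"]).to_csv(
            annotation_path, index=False
        )


def read_annotation_intervals(path, vocabulary=None) -> pd.DataFrame:
    """Read (start_sample, end_sample, label) half-open 0-based intervals."""
    df = pd.read_csv(path)
    required = {"start_sample", "end_sample", "label"}
    if not required.issubset(df.columns):
        raise ValueError(f"{path}: annotation columns must be {sorted(required)}")
    if (df["end_sample"] <= df["start_sample"]).any() or (df["start_sample"] < 0).any():
        raise ValueError(f"{path}: invalid annotation intervals")
    if vocabulary is not None:
        allowed = set(vocabulary) | {TRANSITION_LABEL, UNKNOWN_LABEL}
        bad = set(df["label"].astype(str)) - allowed
        if bad:
            raise ValueError(f"{path}: labels {sorted(bad)} not in vocabulary")
    return df


def expand_annotations(intervals: pd.DataFrame, n_samples: int) -> np.ndarray:
    """Expand intervals to a per-sample label array; gaps become 'unknown'."""
    if (intervals["end_sample"] > n_samples).any():
        raise ValueError(
            "annotation intervals extend past the end of the recording"
        )
    labels = np.full(n_samples, UNKNOWN_LABEL, dtype=object)
    for _, row in intervals.iterrows():
        labels[int(row["start_sample"]) : int(row["end_sample"])] = str(row["label"])
    return labels


def segment_frames(rec: Recording, width: int, overlap: float = 0.5) -> FrameSet:
    """Cut a recording into overlapping frames.

    Frames start at 0, step, 2*step, ... with ``step = round(width*(1-overlap))``;
    trailing samples that do not fill a frame are dropped. When the
    recording is annotated, each frame gets the majority sample label; a
    frame that touches an annotated transition zone, or whose majority vote
    ties, is labeled 'transition'.
    """
    L = rec.n_samples
    if not 0 <= overlap < 1:
        raise ValueError("overlap must be in [0, 1)")
    if width < 1:
        raise ValueError("width must be >= 1")
    if width > L:
        raise ValueError(f"frame width {width} exceeds recording length {L}")
    step = int(round(width * (1.0 - overlap)))
    if step < 1:
        raise ValueError("overlap too large: step rounds to zero samples")
    n_frames = (L - width) // step + 1
    starts = np.arange(n_frames) * step
    frames = np.stack([rec.channels[:, s : s + width] for s in starts])
    frame_labels = None
    if rec.annotations is not None:
        frame_labels = [
            _frame_label(rec.annotations[s : s + width]) for s in starts
        ]
    return FrameSet(frames, width, step, starts, frame_labels, rec.fs)


def _frame_label(sample_labels: np.ndarray) -> str:
    if TRANSITION_LABEL in sample_labels:
        return TRANSITION_LABEL
    counts = Counter(sample_labels.tolist())
    ranked = counts.most_common()
    if len(ranked) > 1 and ranked[0][1] == ranked[1][1]:
        return TRANSITION_LABEL
    return str(ranked[0][0])
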