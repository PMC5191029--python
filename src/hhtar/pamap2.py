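"""PAMAP2-dialect parsing, preprocessing, and sliding-window segmentation.

The on-disk dialect is whitespace-delimited text, 54 columns per row:
timestamp (s), activity ID, heart rate (bpm), then three 17-column IMU
blocks (wrist, chest, ankle).  Within a block: temperature, +-16 g
accelerometer x/y/z, +-6 g accelerometer x/y/z, gyroscope x/y/z,
magnetometer x/y/z, four orientation columns (invalid in this collection).
Only the +-16 g accelerometers of the three IMUs feed the method.

Preprocessing applies three rules: transient rows (activity ID 0) are
dropped; the first 10 s of every contiguous bout of an activity are
dropped (sensor settling / activity onset); and any timepoint missing a
value in any of the 9 used channels is dropped entirely.  Windows of
5.12 s shifted by 1 s are then cut inside contiguous bouts only — a
dropped timepoint breaks the bout, since EMD needs an unbroken series.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .synth import ACC16_COLUMNS, CHANNEL_NAMES, N_COLUMNS

__all__ = [
    "read_pamap2",
    "preprocess",
    "segment",
    "PreprocessedFrames",
    "WindowSet",
    "IMU_FIELDS",
    "RAW_COLUMNS",
]

WARMUP_S = 10.0
DEFAULT_WINDOW_S = 5.12
DEFAULT_SHIFT_S = 1.0

IMU_FIELDS = (
    "temp",
    "acc16_x",
    "acc16_y",
    "acc16_z",
    "acc6_x",
    "acc6_y",
    "acc6_z",
    "gyro_x",
    "gyro_y",
    "gyro_z",
    "mag_x",
    "mag_y",
    "mag_z",
    "orient_1",
    "orient_2",
    "orient_3",
    "orient_4",
)

RAW_COLUMNS = (
    "timestamp",
    "activity_id",
    "heart_rate",
    *(f"wrist_{f}" for f in IMU_FIELDS),
    *(f"chest_{f}" for f in IMU_FIELDS),
    *(f"ankle_{f}" for f in IMU_FIELDS),
)

_USED = [RAW_COLUMNS[c] for c in ACC16_COLUMNS]  # wrist/chest/ankle acc16 x,y,z


class ParseError(ValueError):
    pass


def read_pamap2(path) -> pd.DataFrame:
    """Parse a 54-column whitespace file into typed records.

    NaN tokens become missing markers (float NaN).  A row with a field
    count other than 54 raises ParseError naming the 1-based line number.
    """
    rows: list[list[float]] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            parts = line.split()
            if not parts:
                continue
            if len(parts) != N_COLUMNS:
                raise ParseError(
                    f"line {lineno}: expected {N_COLUMNS} fields, got {len(parts)}"
                )
            try:
                rows.append([float(p) for p in parts])
            except ValueError as exc:
                raise ParseError(f"line {lineno}: {exc}") from None
    data = np.array(rows, dtype=float).reshape(len(rows), N_COLUMNS)
    df = pd.DataFrame(data, columns=list(RAW_COLUMNS))
    df["activity_id"] = df["activity_id"].astype(int)
    return df


@dataclass
class PreprocessedFrames:
    """Cleaned frames: timestamp, activity, 9 channels, contiguous-bout ids.

    Produced by :func:`preprocess`; passing it through preprocess again is
    the identity (the cleaning rules have already been applied and the
    bout structure is frozen in ``bout_id``).
    """

    frames: pd.DataFrame  # timestamp, activity_id, 9 channels, bout_id
    fs: float
    subject_id: int

    def __len__(self) -> int:
        return len(self.frames)


def _assign_bouts(ts: np.ndarray, activity: np.ndarray, fs: float) -> np.ndarray:
    """Bout id per frame: a bout is a maximal run of equal activity with
    timestamp steps of exactly 1/fs (within half a sample of tolerance)."""
    if ts.size == 0:
        return np.zeros(0, dtype=int)
    new = np.ones(ts.size, dtype=bool)
    if ts.size > 1:
        gap = np.diff(ts) > 1.5 / fs
        new[1:] = gap | (activity[1:] != activity[:-1])
    return np.cumsum(new) - 1


def preprocess(
    records: pd.DataFrame | PreprocessedFrames,
    fs: float = 100.0,
    subject_id: int = 0,
) -> PreprocessedFrames:
    """Apply the cleaning rules and keep only the 9 used channels.

    Steps, in order: drop activity-0 rows; drop the first 10 s of every
    contiguous bout of each activity; drop every timepoint with a missing
    value in any used channel; retain timestamp, activity and the +-16 g
    accelerometer channels, with bout ids recomputed so that missing-data
    gaps split bouts.  Idempotent: an already-preprocessed input is
    returned unchanged.
    """
    if isinstance(records, PreprocessedFrames):
        return records
    df = records
    keep = df["activity_id"].to_numpy() != 0
    df = df.loc[keep]
    ts = df["timestamp"].to_numpy(dtype=float)
    activity = df["activity_id"].to_numpy(dtype=int)
    bouts = _assign_bouts(ts, activity, fs)
    # warm-up trim, per bout
    keep = np.ones(ts.size, dtype=bool)
    for b in np.unique(bouts):
        sel = bouts == b
        t0 = ts[sel][0]
        keep[sel] = ts[sel] - t0 >= WARMUP_S
    out = pd.DataFrame(
        {
            "timestamp": ts[keep],
            "activity_id": activity[keep],
        }
    )
    for name in _USED:
        out[name.replace("_acc16", "")] = df[name].to_numpy(dtype=float)[keep]
    out.columns = ["timestamp", "activity_id", *CHANNEL_NAMES]
    # missing-data drop across all 9 used channels
    complete = ~out[list(CHANNEL_NAMES)].isna().any(axis=1).to_numpy()
    out = out.loc[complete].reset_index(drop=True)
    out["bout_id"] = _assign_bouts(
        out["timestamp"].to_numpy(dtype=float),
        out["activity_id"].to_numpy(dtype=int),
        fs,
    )
    return PreprocessedFrames(frames=out, fs=fs, subject_id=int(subject_id))


@dataclass
class WindowSet:
    """Fixed-length windows cut inside contiguous single-activity bouts."""

    data: np.ndarray  # shape (n_windows, 9, L)
    activity: np.ndarray  # (n_windows,)
    subject: np.ndarray  # (n_windows,)
    start_time: np.ndarray  # (n_windows,) seconds
    fs: float
    window: int  # L, samples
    shift: int  # samples

    def __len__(self) -> int:
        return self.data.shape[0]

    @staticmethod
    def concatenate(sets: list["WindowSet"]) -> "WindowSet":
        first = sets[0]
        return WindowSet(
            data=np.concatenate([s.data for s in sets], axis=0),
            activity=np.concatenate([s.activity for s in sets]),
            subject=np.concatenate([s.subject for s in sets]),
            start_time=np.concatenate([s.start_time for s in sets]),
            fs=first.fs,
            window=first.window,
            shift=first.shift,
        )


def _samples(seconds: float, fs: float, what: str) -> int:
    n = seconds * fs
    if abs(n - round(n)) > 1e-9:
        raise ValueError(f"{what} of {seconds} s is not an integral number of samples at fs={fs}")
    return int(round(n))


def segment(
    frames: PreprocessedFrames,
    window_s: float = DEFAULT_WINDOW_S,
    shift_s: float = DEFAULT_SHIFT_S,
) -> WindowSet:
    """Cut sliding windows of ``window_s`` shifted by ``shift_s``.

    Window starts are multiples of the shift within each bout; a window
    never spans a bout boundary or a dropped-frame gap, and carries its
    bout's single activity label.
    """
    fs = frames.fs
    L = _samples(window_s, fs, "window")
    shift = _samples(shift_s, fs, "shift")
    df = frames.frames
    chans = df[list(CHANNEL_NAMES)].to_numpy(dtype=float).T  # (9, n)
    ts = df["timestamp"].to_numpy(dtype=float)
    activity = df["activity_id"].to_numpy(dtype=int)
    bouts = df["bout_id"].to_numpy(dtype=int)
    wins, labs, starts = [], [], []
    for b in np.unique(bouts):
        idx = np.flatnonzero(bouts == b)
        n = idx.size
        for s0 in range(0, n - L + 1, shift):
            sel = idx[s0 : s0 + L]
            wins.append(chans[:, sel])
            labs.append(activity[sel[0]])
            starts.append(ts[sel[0]])
    data = (
        np.stack(wins, axis=0) if wins else np.zeros((0, len(CHANNEL_NAMES), L))
    )
    return WindowSet(
        data=data,
        activity=np.array(labs, dtype=int),
        subject=np.full(len(labs), frames.subject_id, dtype=int),
        start_time=np.array(starts, dtype=float),
        fs=fs,
        window=L,
        shift=shift,
    )
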