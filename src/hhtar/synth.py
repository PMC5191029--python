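"""Synthetic labeled accelerometer streams in the PAMAP2 text dialect.

Real wearable-accelerometer traces are nonlinear and non-stationary; the
generator emulates that character with the simplest family rich enough for
EMD to produce several IMFs per window: per activity bout and channel an
amplitude-modulated, optionally chirped sinusoid plus white Gaussian noise
and a constant (gravity-like) offset.  Distinct activities get distinct
base frequencies, so class identity is carried by spectral content the way
cadence separates, say, walking from running.

Streams carry 9 channels (wrist, chest, ankle x 3 axes at 100 Hz),
per-sample activity labels with activity-0 transients between bouts, and
optional missing values (a whole randomly chosen sensor block NaN'd at a
timepoint, mimicking wireless packet loss).  ``write_pamap2`` serializes a
stream into the 54-column whitespace dialect so the full parsing and
preprocessing path is exercised without any download.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "ActivityClassSpec",
    "StreamConfig",
    "LabeledStream",
    "generate_stream",
    "write_pamap2",
    "demo_classes",
    "demo_config",
]

N_CHANNELS = 9
SENSORS = ("wrist", "chest", "ankle")
AXES = ("x", "y", "z")
CHANNEL_NAMES = tuple(f"{s}_{a}" for s in SENSORS for a in AXES)

# 0-based column index of each used +-16 g accelerometer channel in the
# 54-column row: IMU blocks start at columns 3 (wrist), 20 (chest), 37
# (ankle); within a block the +-16 g accelerometer occupies offsets 1-3.
ACC16_COLUMNS = tuple(base + 1 + k for base in (3, 20, 37) for k in range(3))
N_COLUMNS = 54


class ConfigError(ValueError):
    """An invalid generator configuration; the message names the field."""


def _per_channel(value, name: str) -> np.ndarray:
    arr = np.atleast_1d(np.asarray(value, dtype=float))
    if arr.size == 1:
        return np.full(N_CHANNELS, arr[0])
    if arr.size != N_CHANNELS:
        raise ConfigError(f"{name}: expected a scalar or {N_CHANNELS} values")
    return arr


@dataclass
class ActivityClassSpec:
    """Signal recipe for one activity class.

    Every field may be a scalar (shared by all 9 channels) or a length-9
    sequence ordered wrist/chest/ankle x x/y/z.  Units: base_frequency and
    am_rate in Hz, chirp_rate in Hz/s, amplitude / noise_sd / offset in
    m s^-2; am_depth is a fraction in [0, 1].
    """

    class_id: int
    base_frequency: float | np.ndarray = 2.0
    amplitude: float | np.ndarray = 1.0
    am_depth: float | np.ndarray = 0.0
    am_rate: float | np.ndarray = 0.0
    chirp_rate: float | np.ndarray = 0.0
    noise_sd: float | np.ndarray = 0.0
    offset: float | np.ndarray = 0.0

    def validate(self, fs: float) -> None:
        if int(self.class_id) <= 0:
            raise ConfigError(f"class_id: must be a positive integer, got {self.class_id}")
        f0 = _per_channel(self.base_frequency, "base_frequency")
        if np.any(f0 >= fs / 2.0):
            raise ConfigError(f"base_frequency: must be below fs/2 = {fs / 2.0} Hz")
        if np.any(f0 <= 0):
            raise ConfigError("base_frequency: must be positive")
        depth = _per_channel(self.am_depth, "am_depth")
        if np.any((depth < 0) | (depth > 1)):
            raise ConfigError("am_depth: must lie in [0, 1]")
        if np.any(_per_channel(self.noise_sd, "noise_sd") < 0):
            raise ConfigError("noise_sd: must be >= 0")


@dataclass
class StreamConfig:
    """Multi-bout recording plan for one subject.

    ``schedule`` is an ordered list of (class_id, duration_s) bouts;
    activity-0 transients of ``transient_s`` seconds are inserted between
    consecutive bouts.  ``missing_rate`` is the fraction of timepoints at
    which one randomly chosen sensor block is NaN'd.
    """

    subject_id: int
    schedule: list[tuple[int, float]]
    classes: list[ActivityClassSpec]
    seed: int = 0
    fs: float = 100.0
    missing_rate: float = 0.0
    transient_s: float = 2.0

    def validate(self) -> None:
        if self.fs <= 0:
            raise ConfigError(f"fs: must be positive, got {self.fs}")
        if not self.schedule:
            raise ConfigError("schedule: must be nonempty")
        known = {int(c.class_id) for c in self.classes}
        for cid, dur in self.schedule:
            if dur <= 0:
                raise ConfigError(f"schedule: duration must be > 0, got {dur}")
            if int(cid) not in known:
                raise ConfigError(f"schedule: class_id {cid} has no ActivityClassSpec")
        if not 0.0 <= self.missing_rate < 1.0:
            raise ConfigError(f"missing_rate: must lie in [0, 1), got {self.missing_rate}")
        if self.transient_s < 0:
            raise ConfigError(f"transient_s: must be >= 0, got {self.transient_s}")
        for spec in self.classes:
            spec.validate(self.fs)


@dataclass
class LabeledStream:
    """9-channel 100 Hz stream with per-sample activity IDs."""

    timestamps: np.ndarray
    activity_ids: np.ndarray
    channels: np.ndarray  # shape (9, n)
    subject_id: int
    fs: float

    @property
    def n_samples(self) -> int:
        return self.timestamps.size


def _bout_channels(
    spec: ActivityClassSpec, n: int, fs: float, rng: np.random.Generator
) -> np.ndarray:
    t = np.arange(n) / fs
    f0 = _per_channel(spec.base_frequency, "base_frequency")
    amp = _per_channel(spec.amplitude, "amplitude")
    depth = _per_channel(spec.am_depth, "am_depth")
    am_rate = _per_channel(spec.am_rate, "am_rate")
    chirp = _per_channel(spec.chirp_rate, "chirp_rate")
    noise_sd = _per_channel(spec.noise_sd, "noise_sd")
    offset = _per_channel(spec.offset, "offset")
    out = np.empty((N_CHANNELS, n))
    for c in range(N_CHANNELS):
        phase = 2.0 * np.pi * (f0[c] * t + 0.5 * chirp[c] * t**2)
        envelope = amp[c] * (1.0 + depth[c] * np.sin(2.0 * np.pi * am_rate[c] * t))
        out[c] = envelope * np.sin(phase) + offset[c]
        if noise_sd[c] > 0:
            out[c] += rng.normal(0.0, noise_sd[c], size=n)
    return out


def generate_stream(config: StreamConfig) -> LabeledStream:
    """Deterministically synthesize a labeled multi-bout stream.

    Each bout's channels follow its class recipe with time restarted at the
    bout start; transients carry activity ID 0 and low-level noise only.
    Identical (config, seed) gives identical output.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    fs = config.fs
    by_id = {int(c.class_id): c for c in config.classes}
    n_trans = int(round(config.transient_s * fs))
    pieces: list[np.ndarray] = []
    labels: list[np.ndarray] = []
    for k, (cid, dur) in enumerate(config.schedule):
        if k > 0 and n_trans > 0:
            pieces.append(rng.normal(0.0, 0.05, size=(N_CHANNELS, n_trans)))
            labels.append(np.zeros(n_trans, dtype=int))
        n = int(round(dur * fs))
        pieces.append(_bout_channels(by_id[int(cid)], n, fs, rng))
        labels.append(np.full(n, int(cid), dtype=int))
    channels = np.concatenate(pieces, axis=1)
    activity = np.concatenate(labels)
    n_total = activity.size
    if config.missing_rate > 0:
        hit = rng.random(n_total) < config.missing_rate
        block = rng.integers(0, len(SENSORS), size=n_total)
        for t_idx in np.flatnonzero(hit):
            b = block[t_idx]
            channels[3 * b : 3 * b + 3, t_idx] = np.nan
    return LabeledStream(
        timestamps=np.arange(n_total) / fs,
        activity_ids=activity,
        channels=channels,
        subject_id=int(config.subject_id),
        fs=fs,
    )


def write_pamap2(stream: LabeledStream, path) -> None:
    """Serialize a stream as 54-column whitespace text.

    Accelerometer channels land in the +-16 g slots of each IMU block;
    every unused column (temperature, +-6 g accelerometer, gyroscope,
    magnetometer, orientation, heart rate) carries the literal token NaN,
    matching the published files' missing-value convention.  Channel values
    already NaN (injected missing data) are written as NaN too.
    """
    with open(path, "w") as fh:
        for i in range(stream.n_samples):
            fields = ["NaN"] * N_COLUMNS
            fields[0] = format(stream.timestamps[i], ".17g")
            fields[1] = str(int(stream.activity_ids[i]))
            for c, col in enumerate(ACC16_COLUMNS):
                v = stream.channels[c, i]
                fields[col] = "NaN" if np.isnan(v) else format(v, ".17g")
            fh.write(" ".join(fields) + "\n")


def demo_classes() -> list[ActivityClassSpec]:
    """Four activity classes separated in both cadence and intensity.

    Real activities differ in cadence (base frequency) and in vigor
    (signal amplitude): a posture is a low-amplitude low-frequency signal,
    running a high-amplitude high-frequency one.  The four classes step
    through base frequencies 2/4/6/8 Hz and amplitudes 0.5/1/2/3.5 m s^-2,
    so spectral features (MS) and energy features (IE) each carry class
    information on their own.  30% amplitude modulation at slow per-class
    rates supplies non-stationarity, noise_sd is 10% of each class's
    amplitude (moderate sensor noise), and the z axis of every sensor
    carries a gravity-like 9.81 m s^-2 bias.
    """
    g_offset = [0.0, 0.0, 9.81] * 3
    specs = []
    for cid, (f0, amp, am_rate) in enumerate(
        [(2.0, 0.5, 0.2), (4.0, 1.0, 0.4), (6.0, 2.0, 0.6), (8.0, 3.5, 0.8)],
        start=1,
    ):
        specs.append(
            ActivityClassSpec(
                class_id=cid,
                base_frequency=f0,
                amplitude=amp,
                am_depth=0.3,
                am_rate=am_rate,
                noise_sd=0.1 * amp,
                offset=g_offset,
            )
        )
    return specs


def demo_config(
    seed: int = 0, subject_id: int = 1, bout_s: float = 66.0, missing_rate: float = 0.0
) -> StreamConfig:
    """One subject cycling once through the four demo classes.

    66 s bouts leave 56 s per bout after the 10 s warm-up trim, i.e. 51
    sliding windows per class at the 5.12 s / 1 s segmentation.
    """
    classes = demo_classes()
    return StreamConfig(
        subject_id=subject_id,
        schedule=[(c.class_id, bout_s) for c in classes],
        classes=classes,
        seed=seed,
        missing_rate=missing_rate,
    )
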