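"""Window-level HHT feature assembly.

For each of the 9 accelerometer channels of a window the channel is
EMD-decomposed and Hilbert-analyzed, yielding three scalar streams:

* IE — instantaneous energy density over time,
* MS — marginal spectrum over frequency bins,
* IA/IF of IMFs 3 and 4 — the first two IMFs are treated as high-frequency
  noise, and daily activities live in the low-frequency modes; taking
  fixed positions 3 and 4 keeps the feature dimension constant even though
  the number of IMFs varies from window to window.

The feature of each stream is its mean and population variance, giving per
channel 2 values for IE, 2 for MS, and 8 for IA/IF (2 IMFs x 2 streams x
2 stats); over 9 channels that is 18, 18, and 72 values, combined per the
chosen feature specification (ie, ms, iaif, or any concatenation).

Column order is sensor (wrist, chest, ankle) x axis (x, y, z) x quantity x
statistic, with quantities ordered as in the spec string; consequently the
columns of a smaller spec are an ordered subset of any spec containing it.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import emd, hsa
from .pamap2 import WindowSet
from .synth import CHANNEL_NAMES

__all__ = [
    "FEATURE_SPECS",
    "feature_dimension",
    "feature_names",
    "select_imfs_34",
    "window_features",
    "extract_features",
    "select_spec",
    "normalize_features",
    "FeatureMatrix",
]

FEATURE_SPECS = ("ie", "ms", "iaif", "ie-ms", "ie-iaif", "ms-iaif", "ie-ms-iaif")

_STATS = ("mean", "var")
_QUANTITIES = {
    "ie": ("ie",),
    "ms": ("ms",),
    "iaif": ("ia_imf3", "if_imf3", "ia_imf4", "if_imf4"),
}


def _components(spec: str) -> tuple[str, ...]:
    s = spec.strip().lower()
    if s not in FEATURE_SPECS:
        raise ValueError(f"unknown feature spec {spec!r}; choose from {FEATURE_SPECS}")
    return tuple(s.split("-"))


def feature_dimension(spec: str) -> int:
    """Total feature count for a spec: 18 per scalar stream (IE, MS),
    72 for IA/IF of IMFs 3-4, summed over the spec's components."""
    per_channel = sum(len(_QUANTITIES[c]) * len(_STATS) for c in _components(spec))
    return per_channel * len(CHANNEL_NAMES)


def feature_names(spec: str) -> list[str]:
    comps = _components(spec)
    names = []
    for chan in CHANNEL_NAMES:
        for comp in comps:
            for q in _QUANTITIES[comp]:
                for stat in _STATS:
                    names.append(f"{chan}_{q}_{stat}")
    return names


def select_imfs_34(
    decomp: emd.IMFDecomposition, n_samples: int
) -> tuple[np.ndarray, np.ndarray, bool]:
    """IMFs at positions 3 and 4 (1-based); zero series + flag when the
    decomposition produced fewer than four IMFs."""
    imfs = decomp.imfs
    short = len(imfs) < 4
    c3 = imfs[2] if len(imfs) >= 3 else np.zeros(n_samples)
    c4 = imfs[3] if len(imfs) >= 4 else np.zeros(n_samples)
    return c3, c4, short


def _stream_stats(x: np.ndarray) -> tuple[float, float]:
    return float(np.mean(x)), float(np.var(x))


@dataclass
class _ChannelHHT:
    ie: np.ndarray
    ms: np.ndarray
    ia3: np.ndarray
    if3: np.ndarray
    ia4: np.ndarray
    if4: np.ndarray
    short: bool


def _analyze_channel(x: np.ndarray, fs: float, n_bins: int) -> _ChannelHHT:
    n = x.size
    decomp = emd.decompose(x)
    analytic = [hsa.analytic_signal(c, fs) for c in decomp.imfs]
    ie = hsa.instantaneous_energy(analytic, n_samples=n)
    spectrum = hsa.hilbert_spectrum(analytic, fs, n_bins=n_bins, n_samples=n)
    ms = hsa.marginal_spectrum(spectrum)
    c3, c4, short = select_imfs_34(decomp, n)
    zero = hsa.AnalyticChannel(np.zeros(n), np.zeros(n), np.zeros(n))
    a3 = hsa.analytic_signal(c3, fs) if np.any(c3) else zero
    a4 = hsa.analytic_signal(c4, fs) if np.any(c4) else zero
    return _ChannelHHT(
        ie=ie,
        ms=ms,
        ia3=a3.amplitude,
        if3=a3.frequency,
        ia4=a4.amplitude,
        if4=a4.frequency,
        short=short,
    )


def window_features(
    window: np.ndarray,
    spec: str = "ie-ms-iaif",
    fs: float = 100.0,
    n_bins: int = hsa.DEFAULT_N_BINS,
) -> tuple[np.ndarray, bool]:
    """Feature vector of one 9 x L window, plus a flag set when any channel
    had fewer than four IMFs (its IMF-3/4 slots are zero-filled)."""
    comps = _components(spec)
    window = np.asarray(window, dtype=float)
    if window.ndim != 2 or window.shape[0] != len(CHANNEL_NAMES):
        raise ValueError(f"window must be 9 x L, got shape {window.shape}")
    values: list[float] = []
    short_any = False
    for c in range(window.shape[0]):
        try:
            ch = _analyze_channel(window[c], fs, n_bins)
        except Exception as exc:
            raise RuntimeError(
                f"feature extraction failed on channel {CHANNEL_NAMES[c]}: {exc}"
            ) from exc
        short_any |= ch.short
        streams = {
            "ie": ch.ie,
            "ms": ch.ms,
            "ia_imf3": ch.ia3,
            "if_imf3": ch.if3,
            "ia_imf4": ch.ia4,
            "if_imf4": ch.if4,
        }
        for comp in comps:
            for q in _QUANTITIES[comp]:
                m, v = _stream_stats(streams[q])
                values.extend((m, v))
    return np.array(values), short_any


@dataclass
class FeatureMatrix:
    """Windows x named features with per-row (subject, activity) labels."""

    features: pd.DataFrame
    activity: np.ndarray
    subject: np.ndarray
    start_time: np.ndarray
    spec: str
    flagged: np.ndarray  # rows where some channel had < 4 IMFs

    def __len__(self) -> int:
        return len(self.features)

    def take(self, mask: np.ndarray) -> "FeatureMatrix":
        return FeatureMatrix(
            features=self.features.loc[mask].reset_index(drop=True),
            activity=self.activity[mask],
            subject=self.subject[mask],
            start_time=self.start_time[mask],
            spec=self.spec,
            flagged=self.flagged[mask],
        )

    def to_csv(self, path) -> None:
        out = self.features.copy()
        out.insert(0, "start_time", self.start_time)
        out.insert(0, "activity_id", self.activity)
        out.insert(0, "subject_id", self.subject)
        out.to_csv(path, index=False)


def extract_features(
    windows: WindowSet,
    spec: str = "ie-ms-iaif",
    n_bins: int = hsa.DEFAULT_N_BINS,
) -> FeatureMatrix:
    """Feature matrix for a window set, in window order."""
    names = feature_names(spec)
    rows = np.zeros((len(windows), len(names)))
    flags = np.zeros(len(windows), dtype=bool)
    for i in range(len(windows)):
        rows[i], flags[i] = window_features(
            windows.data[i], spec=spec, fs=windows.fs, n_bins=n_bins
        )
    return FeatureMatrix(
        features=pd.DataFrame(rows, columns=names),
        activity=windows.activity.copy(),
        subject=windows.subject.copy(),
        start_time=windows.start_time.copy(),
        spec=spec,
        flagged=flags,
    )


def select_spec(matrix: FeatureMatrix, spec: str) -> FeatureMatrix:
    """Project a feature matrix onto a smaller spec by column selection.

    Valid whenever every component of ``spec`` is present in the matrix's
    spec; the per-window computation is identical, so the result equals
    extracting with ``spec`` directly.
    """
    names = feature_names(spec)
    missing = [n for n in names if n not in matrix.features.columns]
    if missing:
        raise ValueError(f"matrix (spec {matrix.spec!r}) lacks columns for {spec!r}")
    return FeatureMatrix(
        features=matrix.features[names].copy(),
        activity=matrix.activity.copy(),
        subject=matrix.subject.copy(),
        start_time=matrix.start_time.copy(),
        spec=spec,
        flagged=matrix.flagged.copy(),
    )


@dataclass
class NormStats:
    mean: pd.Series
    sd: pd.Series


def normalize_features(
    train: FeatureMatrix, apply_to: FeatureMatrix
) -> tuple[FeatureMatrix, NormStats]:
    """Z-score ``apply_to`` with the training set's column mean/SD.

    Zero-SD (constant) columns are centered but not divided.
    """
    if len(train) == 0:
        raise ValueError("training matrix is empty")
    mean = train.features.mean(axis=0)
    sd = train.features.std(axis=0, ddof=0)
    safe_sd = sd.where(sd > 0, 1.0)
    out = (apply_to.features - mean) / safe_sd
    return (
        FeatureMatrix(
            features=out,
            activity=apply_to.activity.copy(),
            subject=apply_to.subject.copy(),
            start_time=apply_to.start_time.copy(),
            spec=apply_to.spec,
            flagged=apply_to.flagged.copy(),
        ),
        NormStats(mean=mean, sd=sd),
    )
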