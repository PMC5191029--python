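"""Hilbert spectral analysis of intrinsic mode functions.

Each IMF is extended to an analytic signal z(t) = x(t) + i y(t) with y the
Hilbert transform of x; its modulus gives the instantaneous amplitude (IA)
and the derivative of its unwrapped phase gives the instantaneous frequency
(IF).  Placing each IMF's amplitude at its instantaneous frequency builds
the Hilbert spectrum H(f, t), from which follow

* the marginal spectrum  h(f) = sum_t H(f, t) * dt,
* the instantaneous energy density  IE(t) = sum_i a_i(t)^2,
* the degree of stationarity  DS(f) = mean_t (1 - H(f, t)/n(f))^2
  with n(f) = h(f)/T — zero exactly when H is constant in time at f.

Frequencies are in Hz throughout.  IE is computed directly from the IMF
amplitudes (unit bin-width convention) so it does not depend on the grid;
the gridded cross-check in the tests applies the bin width explicitly.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.ndimage import convolve
from scipy.signal import hilbert as _hilbert

__all__ = [
    "AnalyticChannel",
    "HilbertSpectrum",
    "analytic_signal",
    "instantaneous_frequency",
    "hilbert_spectrum",
    "marginal_spectrum",
    "instantaneous_energy",
    "degree_of_stationarity",
    "smooth_spectrum",
]

#: Default number of frequency bins for 512-sample windows.
DEFAULT_N_BINS = 256
#: Gaussian smoothing kernel: 9x9 support, sigma in bins.
SMOOTH_SIZE = 9
SMOOTH_SIGMA = 1.5


@dataclass
class AnalyticChannel:
    """IA / unwrapped phase / IF of one IMF."""

    amplitude: np.ndarray
    phase: np.ndarray
    frequency: np.ndarray

    def __len__(self) -> int:
        return self.amplitude.size


@dataclass
class HilbertSpectrum:
    """Time x frequency amplitude grid with uniform bins over [0, f_max]."""

    H: np.ndarray  # shape (n_times, n_bins)
    freq_edges: np.ndarray  # length n_bins + 1
    dt: float
    df: float

    @property
    def n_times(self) -> int:
        return self.H.shape[0]

    @property
    def n_bins(self) -> int:
        return self.H.shape[1]

    @property
    def freq_centers(self) -> np.ndarray:
        return 0.5 * (self.freq_edges[:-1] + self.freq_edges[1:])


def analytic_signal(imf: np.ndarray, fs: float) -> AnalyticChannel:
    """Analytic-signal IA, unwrapped phase, and IF of one IMF.

    The imaginary part is the discrete Hilbert transform computed through
    the frequency-domain analytic-signal construction.
    """
    imf = np.asarray(imf, dtype=float)
    if imf.size < 8:
        raise ValueError(f"IMF too short for analytic signal: {imf.size} < 8")
    z = _hilbert(imf)
    amplitude = np.abs(z)
    phase = np.unwrap(np.angle(z))
    frequency = instantaneous_frequency(phase, fs)
    return AnalyticChannel(amplitude=amplitude, phase=phase, frequency=frequency)


def instantaneous_frequency(phase: np.ndarray, fs: float) -> np.ndarray:
    """IF in Hz from an unwrapped phase: central differences of the phase
    (one-sided at the ends) divided by 2*pi."""
    phase = np.asarray(phase, dtype=float)
    return np.gradient(phase) * fs / (2.0 * np.pi)


def hilbert_spectrum(
    channels: list[AnalyticChannel],
    fs: float,
    n_bins: int = DEFAULT_N_BINS,
    f_max: float | None = None,
    n_samples: int | None = None,
) -> HilbertSpectrum:
    """Accumulate per-IMF amplitudes into a time-frequency grid.

    At each sample the amplitude of each IMF is added into the bin holding
    its instantaneous frequency; frequencies outside [0, f_max] (f_max
    defaults to fs/2) are clipped into the nearest edge bin.
    """
    if n_bins < 2:
        raise ValueError(f"n_bins must be >= 2, got {n_bins}")
    if f_max is None:
        f_max = fs / 2.0
    if channels:
        n_t = len(channels[0])
        for ch in channels:
            if len(ch) != n_t:
                raise ValueError("all channels must have equal length")
    else:
        n_t = 0 if n_samples is None else int(n_samples)
    edges = np.linspace(0.0, f_max, n_bins + 1)
    df = edges[1] - edges[0]
    H = np.zeros((n_t, n_bins))
    for ch in channels:
        idx = np.clip(np.floor(ch.frequency / df).astype(int), 0, n_bins - 1)
        np.add.at(H, (np.arange(n_t), idx), ch.amplitude)
    return HilbertSpectrum(H=H, freq_edges=edges, dt=1.0 / fs, df=df)


def marginal_spectrum(spectrum: HilbertSpectrum) -> np.ndarray:
    """h(f): time integral of the Hilbert spectrum per frequency bin."""
    return spectrum.H.sum(axis=0) * spectrum.dt


def instantaneous_energy(
    channels: list[AnalyticChannel], n_samples: int | None = None
) -> np.ndarray:
    """IE(t): sum of squared instantaneous amplitudes over IMFs."""
    if not channels:
        return np.zeros(0 if n_samples is None else int(n_samples))
    n_t = len(channels[0])
    ie = np.zeros(n_t)
    for ch in channels:
        if len(ch) != n_t:
            raise ValueError("all channels must have equal length")
        ie += ch.amplitude**2
    return ie


def degree_of_stationarity(
    spectrum: HilbertSpectrum,
) -> tuple[np.ndarray, np.ndarray]:
    """DS(f) and a defined-mask over frequency bins.

    DS(f) is the mean over time of (1 - H(f,t)/n(f))^2 where n(f) is the
    time mean of H at f.  Bins never visited (n(f) = 0) are undefined: the
    mask is False there and DS reports 0.
    """
    H = spectrum.H
    if H.shape[0] == 0:
        z = np.zeros(H.shape[1])
        return z, np.zeros(H.shape[1], dtype=bool)
    n_f = H.mean(axis=0)  # equals h(f)/T
    defined = n_f > 0
    ds = np.zeros(H.shape[1])
    ratio = H[:, defined] / n_f[defined]
    ds[defined] = np.mean((1.0 - ratio) ** 2, axis=0)
    return ds, defined


def _gaussian_kernel(size: int, sigma: float) -> np.ndarray:
    half = (size - 1) / 2.0
    ax = np.arange(size) - half
    g = np.exp(-(ax**2) / (2.0 * sigma**2))
    k = np.outer(g, g)
    return k / k.sum()


def smooth_spectrum(spectrum: HilbertSpectrum) -> HilbertSpectrum:
    """Visualization-only smoothing with a normalized 9x9 Gaussian kernel
    (reflective borders).  Never feeds feature extraction."""
    H = spectrum.H
    if H.shape[0] < SMOOTH_SIZE or H.shape[1] < SMOOTH_SIZE:
        warnings.warn(
            "grid smaller than the 9x9 smoothing kernel; returned unchanged",
            stacklevel=2,
        )
        return spectrum
    kernel = _gaussian_kernel(SMOOTH_SIZE, SMOOTH_SIGMA)
    smoothed = convolve(H, kernel, mode="reflect")
    return HilbertSpectrum(
        H=smoothed,
        freq_edges=spectrum.freq_edges.copy(),
        dt=spectrum.dt,
        df=spectrum.df,
    )
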