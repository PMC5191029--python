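"""Empirical mode decomposition by cubic-spline sifting.

EMD splits a signal into intrinsic mode functions (IMFs) — components whose
extrema and zero-crossing counts differ by at most one and whose local
envelope mean is (numerically) zero — plus a low-frequency residue.  The
decomposition is fully data-driven: each sifting pass subtracts the mean of
the cubic-spline envelopes through the local maxima and minima, and passes
repeat until Huang's standard-deviation criterion falls below ``sd_stop``.
Successive IMFs are extracted from the running residue until it is monotone,
has too few extrema to envelope, or carries negligible energy.

The sum of all IMFs plus the residue reproduces the input to floating-point
accuracy (a telescoping identity of the sifting recursion).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.interpolate import CubicSpline

__all__ = [
    "SiftResult",
    "IMFDecomposition",
    "find_extrema",
    "envelope_mean",
    "is_imf",
    "sift",
    "decompose",
]

#: Huang's sifting stop threshold on SD(h_{k-1}, h_k).
SD_STOP = 0.2
#: Hard cap on sifting passes per IMF.
MAX_SIFTS = 10
#: Residue energy fraction below which extraction stops.
RESIDUE_ENERGY_FRAC = 1e-6
#: Hard cap on the number of extracted IMFs.
MAX_IMFS = 12
#: Envelope-mean tolerance for the IMF test: mean(|m|) < tol * RMS(x).
ENVELOPE_MEAN_TOL = 0.05
#: Number of extrema mirrored past each end before spline fitting.
N_MIRROR = 2


class MonotonicResidueError(ValueError):
    """Raised when a series has too few extrema to build both envelopes."""


@dataclass
class SiftResult:
    """Candidate IMF produced by repeated sifting of one component."""

    h: np.ndarray
    sift_count: int
    is_imf: bool


@dataclass
class IMFDecomposition:
    """Ordered IMFs (highest frequency first) plus the residue trend."""

    imfs: list[np.ndarray]
    residue: np.ndarray
    sift_counts: list[int] = field(default_factory=list)
    converged: list[bool] = field(default_factory=list)

    @property
    def n_imfs(self) -> int:
        return len(self.imfs)

    def reconstruct(self) -> np.ndarray:
        out = self.residue.copy()
        for c in self.imfs:
            out += c
        return out


def _compress_plateaus(x: np.ndarray):
    """Run-length encode equal-valued runs; each run is represented once.

    Returns (values, midpoints) where the midpoint of a run breaks ties
    toward the earlier index.
    """
    x = np.asarray(x, dtype=float)
    n = x.size
    change = np.empty(n, dtype=bool)
    change[0] = True
    change[1:] = x[1:] != x[:-1]
    starts = np.flatnonzero(change)
    ends = np.append(starts[1:], n) - 1
    mids = (starts + ends) // 2
    return x[starts], mids


def find_extrema(x: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Indices of strict local maxima and minima of ``x``.

    Plateaus (runs of equal samples) contribute a single extremum at the
    run midpoint; endpoints are never extrema.
    """
    x = np.asarray(x, dtype=float)
    if x.size < 3:
        return np.empty(0, dtype=int), np.empty(0, dtype=int)
    v, mids = _compress_plateaus(x)
    if v.size < 3:
        return np.empty(0, dtype=int), np.empty(0, dtype=int)
    left = v[1:-1] - v[:-2]
    right = v[1:-1] - v[2:]
    maxima = mids[1:-1][(left > 0) & (right > 0)]
    minima = mids[1:-1][(left < 0) & (right < 0)]
    return maxima.astype(int), minima.astype(int)


def _mirrored_spline(idx: np.ndarray, val: np.ndarray, n: int) -> np.ndarray:
    """Cubic spline through extrema, mirror-extended past both ends.

    Extrema are reflected about the first and last sample so the spline is
    interpolated (never extrapolated) across the whole support.
    """
    k = min(N_MIRROR, idx.size)
    left_idx = -idx[:k][::-1]
    left_val = val[:k][::-1]
    right_idx = 2 * (n - 1) - idx[-k:][::-1]
    right_val = val[-k:][::-1]
    xs = np.concatenate([left_idx, idx, right_idx]).astype(float)
    ys = np.concatenate([left_val, val, right_val])
    # Mirroring can duplicate an abscissa when an extremum sits on a boundary.
    xs, keep = np.unique(xs, return_index=True)
    ys = ys[keep]
    if xs.size < 2:
        raise MonotonicResidueError("too few distinct envelope knots")
    spline = CubicSpline(xs, ys)
    return spline(np.arange(n))


def envelope_mean(x: np.ndarray) -> np.ndarray:
    """Mean of the upper and lower cubic-spline envelopes of ``x``.

    Raises
    ------
    MonotonicResidueError
        If there are fewer than two maxima or two minima, i.e. the series
        is a residue from which no further IMF can be sifted.
    """
    x = np.asarray(x, dtype=float)
    maxima, minima = find_extrema(x)
    if maxima.size < 2 or minima.size < 2:
        raise MonotonicResidueError(
            f"need >= 2 maxima and minima, got {maxima.size} and {minima.size}"
        )
    upper = _mirrored_spline(maxima, x[maxima], x.size)
    lower = _mirrored_spline(minima, x[minima], x.size)
    return 0.5 * (upper + lower)


def _zero_crossings(x: np.ndarray) -> int:
    s = np.sign(x)
    s = s[s != 0]
    if s.size < 2:
        return 0
    return int(np.count_nonzero(s[1:] != s[:-1]))


def is_imf(x: np.ndarray, tol: float = ENVELOPE_MEAN_TOL) -> bool:
    """IMF test: extrema/zero-crossing counts within one of each other and
    envelope mean numerically zero (mean(|m|) < tol * RMS)."""
    x = np.asarray(x, dtype=float)
    if x.size < 3:
        return False
    maxima, minima = find_extrema(x)
    n_ext = maxima.size + minima.size
    if n_ext == 0:
        return False
    if abs(n_ext - _zero_crossings(x)) > 1:
        return False
    try:
        m = envelope_mean(x)
    except MonotonicResidueError:
        return False
    rms = float(np.sqrt(np.mean(x**2)))
    if rms == 0.0:
        return False
    return float(np.mean(np.abs(m))) < tol * rms


def sift(
    x: np.ndarray,
    sd_stop: float = SD_STOP,
    max_sifts: int = MAX_SIFTS,
) -> SiftResult:
    """Extract one candidate IMF from ``x`` by repeated envelope-mean removal.

    Iterates ``h <- h - envelope_mean(h)`` until the standard-deviation
    criterion ``SD = sum((h_prev - h)^2 / h_prev^2) < sd_stop`` holds or
    ``max_sifts`` passes have run; in the latter case the candidate is
    returned with ``is_imf`` reporting whether it meets the IMF test.
    """
    h = np.asarray(x, dtype=float).copy()
    k = 0
    for _ in range(max_sifts):
        try:
            m = envelope_mean(h)
        except MonotonicResidueError:
            break
        h_new = h - m
        k += 1
        denom = h**2
        sd = float(np.sum((h - h_new) ** 2 / (denom + 1e-12)))
        h = h_new
        if sd < sd_stop:
            break
    return SiftResult(h=h, sift_count=k, is_imf=is_imf(h))


def decompose(
    x: np.ndarray,
    max_imfs: int = MAX_IMFS,
    sd_stop: float = SD_STOP,
    max_sifts: int = MAX_SIFTS,
    residue_energy_frac: float = RESIDUE_ENERGY_FRAC,
) -> IMFDecomposition:
    """Full EMD of ``x``: IMFs until the residue is a trend.

    Extraction stops when the residue has fewer than two maxima or minima
    (monotone trend), when its energy drops below
    ``residue_energy_frac`` times the input energy, or at ``max_imfs``.
    A constant or monotone input yields zero IMFs with residue equal to
    the input.
    """
    x = np.asarray(x, dtype=float)
    if x.size < 16:
        raise ValueError(f"series too short for EMD: {x.size} < 16")
    energy0 = float(np.sum(x**2))
    residue = x.copy()
    imfs: list[np.ndarray] = []
    counts: list[int] = []
    converged: list[bool] = []
    while len(imfs) < max_imfs:
        maxima, minima = find_extrema(residue)
        if maxima.size < 2 or minima.size < 2:
            break
        if energy0 > 0 and float(np.sum(residue**2)) < residue_energy_frac * energy0:
            break
        result = sift(residue, sd_stop=sd_stop, max_sifts=max_sifts)
        if result.sift_count == 0:
            break
        imfs.append(result.h)
        counts.append(result.sift_count)
        converged.append(result.is_imf)
        residue = residue - result.h
    return IMFDecomposition(
        imfs=imfs, residue=residue, sift_counts=counts, converged=converged
    )
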