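"""Independent minimal EMD used only as a cross-check oracle.

Deliberately implemented with different primitives than the package:
extrema via scipy.signal.argrelextrema (no plateau handling), envelopes
via InterpolatedUnivariateSpline with the series endpoints appended as
knots (clamped-end rule instead of mirror extension), and a fixed number
of sifting passes instead of a standard-deviation stop.  Agreement is
therefore only expected away from the window ends and for signals whose
components are well separated in frequency.
"""

import numpy as np
from scipy.interpolate import InterpolatedUnivariateSpline
from scipy.signal import argrelextrema


def oracle_envelope_mean(x: np.ndarray) -> np.ndarray:
    n = x.size
    t = np.arange(n)
    mx = argrelextrema(x, np.greater)[0]
    mn = argrelextrema(x, np.less)[0]
    if mx.size < 2 or mn.size < 2:
        raise ValueError("too few extrema")

    def env(idx):
        knots = np.concatenate([[0], idx, [n - 1]])
        vals = x[np.concatenate([[0], idx, [n - 1]])]
        knots, keep = np.unique(knots, return_index=True)
        k = min(3, knots.size - 1)
        return InterpolatedUnivariateSpline(knots, vals[keep], k=k)(t)

    return 0.5 * (env(mx) + env(mn))


def oracle_sift(x: np.ndarray, n_passes: int = 8) -> np.ndarray:
    h = x.astype(float).copy()
    for _ in range(n_passes):
        try:
            m = oracle_envelope_mean(h)
        except ValueError:
            break
        h = h - m
    return h


def oracle_decompose(x: np.ndarray, max_imfs: int = 6):
    residue = x.astype(float).copy()
    imfs = []
    for _ in range(max_imfs):
        mx = argrelextrema(residue, np.greater)[0]
        mn = argrelextrema(residue, np.less)[0]
        if mx.size < 2 or mn.size < 2:
            break
        c = oracle_sift(residue)
        imfs.append(c)
        residue = residue - c
    return imfs, residue
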