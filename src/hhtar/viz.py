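"""Rendering of Hilbert spectra as time-frequency color maps."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

from .hsa import HilbertSpectrum, smooth_spectrum

__all__ = ["plot_spectrum"]


def plot_spectrum(
    spectrum: HilbertSpectrum,
    path,
    smoothed: bool = True,
    title: str | None = None,
) -> None:
    """Write a color-map image of the spectrum to ``path``.

    With ``smoothed`` the 9x9 Gaussian visualization filter is applied
    first (the underlying spectrum is left untouched).
    """
    spec = smooth_spectrum(spectrum) if smoothed else spectrum
    t_max = spec.n_times * spec.dt
    fig, ax = plt.subplots(figsize=(7, 4))
    im = ax.imshow(
        spec.H.T,
        origin="lower",
        aspect="auto",
        extent=(0.0, t_max, spec.freq_edges[0], spec.freq_edges[-1]),
        cmap="viridis",
    )
    ax.set_xlabel("time (s)")
    ax.set_ylabel("frequency (Hz)")
    if title:
        ax.set_title(title)
    fig.colorbar(im, ax=ax, label="amplitude")
    fig.tight_layout()
    fig.savefig(path, dpi=100)
    plt.close(fig)
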