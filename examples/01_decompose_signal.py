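"""Empirical mode decomposition of a two-tone signal.

Builds 10 s of a 1 Hz + 8 Hz mixture sampled at 100 Hz, decomposes it
into intrinsic mode functions, and checks that the components recover the
tones and sum back to the input.
"""

import numpy as np

from hhtar import emd

fs = 100.0
t = np.arange(1000) / fs
lo = np.sin(2 * np.pi * 1 * t)
hi = 0.5 * np.sin(2 * np.pi * 8 * t)
x = lo + hi

d = emd.decompose(x)
recon_err = np.linalg.norm(d.reconstruct() - x) / np.linalg.norm(x)
sl = slice(100, 900)  # interior samples, away from boundary effects

print(f"IMFs extracted:        {d.n_imfs}")
print(f"reconstruction error:  {recon_err:.2e}  (relative L2)")
print(f"IMF1 vs 8 Hz tone r =  {np.corrcoef(d.imfs[0][sl], hi[sl])[0, 1]:.4f}")
best_lo = max(np.corrcoef(c[sl], lo[sl])[0, 1] for c in d.imfs[1:])
print(f"best IMF vs 1 Hz  r =  {best_lo:.4f}")
print()
print("The first IMF carries the highest frequency; the reconstruction")
print("error reflects the telescoping identity of sifting (exact to float")
print("precision), and correlations near 1 mean the tones were isolated.")
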