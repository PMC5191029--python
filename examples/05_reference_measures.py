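"""Macro measures of the packaged 12-activity reference matrices.

The package ships the two published confusion matrices for the PAMAP2
IE-feature experiment; this recomputes their recall, precision, harmonic
mean, and trace/total, and shows both row/column orientations.
"""

from hhtar import evaluation

ref = evaluation.reference_confusions()
print("matrix  recall  precision  harmonic  trace/total   (as_printed)")
for key in ("train", "test"):
    pm = evaluation.measures(ref[key])
    print(f"{key:6s}  {pm.recall:.4f}  {pm.precision:.4f}     {pm.f_measure:.4f}    "
          f"{pm.accuracy:.4f}")
pm_eq = evaluation.measures(ref["train"], orientation="as_equations")
print(f"\ntrain, as_equations orientation: recall={pm_eq.recall:.4f} "
      f"precision={pm_eq.precision:.4f}")
print()
print("as_printed matches the published summary values; the published")
print("summary prints its harmonic-mean and trace/total columns under")
print("interchanged headers, and as_equations swaps recall/precision")
print("(the transposed reading of the defining ratios).")
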