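# Methods

This note records the model, the numerical conventions, and the design
choices made where the method description left the design open. It
states no empirical result that the test suite or `scripts/acceptance.py`
does not itself compute.

## Empirical mode decomposition

Sifting subtracts the mean of the cubic-spline envelopes through the
local maxima and minima (`h ← h − m`) until Huang's standard-deviation
criterion `SD = Σ (h_{k−1} − h_k)² / h_{k−1}²  < 0.2` holds, with a hard
cap of 10 passes per IMF. IMFs are extracted from the running residue
until it has fewer than two maxima or two minima (a monotone trend), its
energy falls below 1e−6 of the input energy, or 12 IMFs have been
produced (ample for 512-sample windows). The reconstruction identity
`Σ c_i + r_n = X` holds to floating-point accuracy by construction and is
asserted at 1e−9 relative L2 in the tests.

Conventions the canonical description leaves open:

* **Boundary handling.** Two extrema are mirrored about each end of the
  series before spline fitting, the usual mitigation for envelope
  overshoot at the window edges. End effects are still the dominant error
  source, which is why tone-based assertions are made on interior
  samples.
* **Envelope-mean tolerance.** The defining "envelope mean equals zero"
  is unattainable numerically; an IMF candidate passes when
  `mean(|m|) < 0.05 · RMS(x)`.
* **Plateaus.** A run of equal samples contributes one extremum at its
  midpoint, ties toward the earlier index.
* **Degenerate inputs.** Constant or monotone series yield zero IMFs
  with residue equal to the input; series shorter than 16 samples are
  rejected.

## Hilbert spectral analysis

The analytic signal is built by the frequency-domain construction
(`scipy.signal.hilbert`); IA is its modulus and IF the central-difference
derivative of the unwrapped phase (one-sided at the ends), reported in Hz
— the figure convention for this application — rather than rad/s.

The Hilbert spectrum accumulates, at every sample, each IMF's amplitude
into the frequency bin containing its IF: 256 uniform bins over
[0, fs/2] = [0, 50] Hz by default for 512-sample windows. Negative
instantaneous frequencies, possible from numerical differentiation near
amplitude nulls, are clipped into the lowest bin. The marginal spectrum
is `h(f) = Σ_t H(f,t)·Δt`.

IE is computed directly from the amplitudes, `IE(t) = Σ_i a_i(t)²`,
a unit-bin-width convention that makes it independent of the grid; any
constant factor cancels after feature normalization. The gridded
cross-check in the tests compares `Σ_f H²` against IE where no two IMFs
share a bin.

DS uses `n(f) = h(f)/T` (the time mean of `H` at `f`); bins never visited
report DS = 0 with a defined-mask rather than NaN, keeping profiles
finite and plottable. The 9×9 Gaussian smoothing (σ = 1.5 bins, kernel
normalized to unit sum, reflective borders) exists for visualization only
and never feeds features.

## Features

Per channel and window: mean and population variance (divide by N) of
the IE series, of the 256-bin MS profile, and of the IA and IF series of
IMFs 3 and 4. IMFs 1–2 are treated as high-frequency noise; positions
3–4 are fixed so the feature dimension stays constant although the IMF
count varies. Windows whose decomposition yields fewer than four IMFs
get zero series in the missing slots and are flagged rather than
discarded, keeping window counts deterministic. Statistics are taken
over the full window (no interior trimming): the end-effect bias is
identical across classes and removed by z-scoring. Column order is
sensor (wrist, chest, ankle) × axis (x, y, z) × quantity × statistic,
which makes every smaller specification an ordered column subset of any
specification containing it. DS is computed and exported for analysis
but is not a classifier feature.

Feature normalization is per-column z-scoring with training-set
statistics (constant columns are centered only); the method description
is silent on scaling, and z-scoring is the standard choice for networks
with sigmoid hidden units.

## Classifier

Three layers: hidden `O_j = logsig(Σ w_ij O_i − θ_j)`, output
`y_k = Σ w_jk O_j − θ_k` (linear), one-hot targets, prediction by argmax
with ties toward the lower class index. Hidden width
`m = ⌊√(x·y)⌋` reproduces all five published architectures for the
12-class benchmark. Initial weights and thresholds are uniform in
`[−0.5, 0.5]/√x`, deterministic per seed.

Training is full-batch gradient descent on the batch mean of
`E = ½ Σ_k (d_k − y_k)²` at learning rate η = 0.1 — the equations as
printed, with batching chosen for determinism over per-pattern updates.
The hidden-layer delta is the standard back-propagated one and is
verified against central finite differences at 1e−5 relative error.
Stopping: MSE goal 1e−3, epoch cap 20 000. The cap is sized so that the
MSE goal, not the cap, normally terminates training: at η = 0.1 the
18-feature problems need roughly 1.5 × 10⁴ epochs to reach the goal, and
stopping earlier leaves the network visibly underfit. Levenberg–Marquardt
(`mode="lm"`, via `scipy.optimize.least_squares` with an analytic residual
Jacobian) is provided as the faster quasi-Newton option historically used
for such networks; the default remains gd because it is fully specified
by the printed update equations.

## Evaluation

Confusion matrices are rows = recognized, columns = annotated. The
default `as_printed` orientation (recall = mean diagonal/row-sum,
precision = mean diagonal/column-sum) reproduces the published summary
values of the packaged reference matrices; `as_equations` swaps the two,
matching the literal reading of the defining ratios — the two differ by
a transpose, and both are exposed. The published summary table also
prints its harmonic-mean and trace/total columns under interchanged
headers; the package reproduces the numbers and documents the mapping
without asserting which header is correct. A class with zero row or
column total contributes 0 to its macro mean, keeping the 1/C factor
fixed.

The dependent protocol splits each (subject, activity) group's windows
chronologically in half (earlier half train), pooled across subjects;
the independent protocol applies the same split within each subject and
trains one model per subject, aggregating measures by test-sample weight
`N_i/N`.

## Preprocessing conventions

A bout is a maximal run of frames with equal activity ID and timestamp
steps of exactly 1/fs; the 10 s warm-up trim applies per bout (the
conservative reading of "discard the first 10 s"). A timepoint missing
any of the 9 used channels is dropped entirely, and the resulting gap
splits the bout — windows never span gaps, since EMD assumes a
contiguous series. Timestamps are assumed regular at 100 Hz and are not
resampled. `preprocess` maps raw records to a distinct preprocessed
container carrying bout ids; applying it to an already-preprocessed
container is the identity, which is how idempotence is guaranteed (the
warm-up trim alone cannot be idempotent on raw frames).

## Synthetic data

The generator emulates labeled multi-sensor recordings with the simplest
family that is non-stationary enough to exercise the whole chain: per
bout and channel an amplitude-modulated, optionally chirped sinusoid
plus white Gaussian noise and a constant gravity-like offset, with
activity-0 transients (default 2 s) between bouts and optional
whole-sensor-block missing values. The default 4-class conditions vary
both cadence (2/4/6/8 Hz) and intensity (amplitudes 0.5/1/2/3.5 m s⁻²,
noise 10% of amplitude): real activities differ along both axes, and the
energy features specifically encode intensity — classes differing only
in frequency would be invisible to IE. One subject cycling once through
the four classes in 66 s bouts gives 51 windows per class after the
trim, sized to keep the full end-to-end run (about 2 000 channel
decompositions) within a few minutes on one CPU.

What the generator does **not** emulate: biomechanical gait structure,
harmonic-rich impact signatures, sensor drift and orientation change,
subject-to-subject variability beyond seeds, heart-rate channels.
Passing end-to-end tests therefore demonstrate that the implementation
chain is correct and that the features separate spectrally/energetically
distinct classes — not that the method attains any particular accuracy
on real recordings. The published whole-dataset scores require the
optional PAMAP2 download workflow described in the README and are not
asserted anywhere in the tests.

## Known limitations

* EMD end effects bias IA/IF near window boundaries; features use full
  windows, relying on normalization to absorb the shared bias.
* The sifting cap (10 passes) can leave an occasional candidate short of
  the strict IMF test; such components are flagged, not dropped.
* Gradient-descent training is slow near the MSE goal on small feature
  sets; `mode="lm"` converges in far fewer iterations but can overfit
  interpolating solutions on tiny training sets.
* The marginal spectrum depends on the bin count through binning only;
  tone-fixture binning error shrinks as bins grow (asserted in tests),
  but MS features always use the 256-bin default for comparability.
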