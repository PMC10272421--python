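# Methods

This note records the models implemented in `mieeg`, the choices made where
the design was genuinely open, and what the synthetic benchmarks do and do
not establish.

## Preprocessing

Continuous or trial-cut EEG is repaired (NaNs replaced by the containing
channel's mean over its remaining samples — channels have different offsets
and scales, so a per-channel mean is the defensible reading of "average of
all sample points"; an all-NaN channel is an error), bandpassed 1–38 Hz with
a 5th-order Butterworth filter, z-scored, epoched (4-s windows from each cue
onset; 1000 samples at 250 Hz), and decomposed by a 10-band filter bank
(1–4 … 35–38 Hz, same filter family).

Open choices, with the defaults shipped:

* **Standardization divisor.** The normalization is described as z-scoring
  but typeset with a variance denominator. The default divides by the
  standard deviation (`zscore(..., divisor="std")`); `"var"` is available.
  Statistics are per channel, pooled over all training trials and time
  points, and must come from the training split.
* **Filter application.** Zero-phase forward–backward filtering
  (`sosfiltfilt`, doubling the effective order) is the default, as usual for
  offline MI analysis; a causal single pass is a flag. Filters are applied
  to continuous data before epoching when cue timing is available, otherwise
  to whole trials.

## Filter-bank OVR-CSP with LASSO selection

Per band and class, the mean trace-normalized covariance
`R_c = (1/N_c) Σ X Xᵀ / tr(X Xᵀ)` enters the generalized eigenproblem
`R_c w = λ R_c̄ w` against the mean of the remaining classes' covariances
(`R_c̄` ridge-conditioned by `1e-8 · tr` for rank-deficient small-sample
cases). Eigenvectors are sorted by descending eigenvalue (stable sort,
original index as tie-break; sign fixed so each column's largest-magnitude
entry is positive), and the top `m = 4` are retained: 4 classes × 4
eigenvectors × 10 bands = 160 columns.

The per-column feature is the standard log-normalized projected variance
`f_j = log(var_j / Σ_{j' in same sub-filter} var_{j'})` (the feature form is
not pinned down by the description; this is the universal CSP choice and is
scale-invariant). Features are column-standardized before the L1 step
because L1 penalties are scale-sensitive.

Selection is a single LASSO on the numeric class labels (1–4), exactly the
printed objective `(1/2N)‖y − β₀ − Fβ‖² + λ‖β‖₁` (scikit-learn's `Lasso`
implements this objective verbatim). Treating a 4-way label ordinally is
statistically odd but is the stated procedure; an one-vs-rest variant
(union of per-class supports) is available behind `ovr=True`. λ defaults to
5-fold cross-validated selection over a log grid (`lam="auto"`); any fixed
positive value is accepted. Columns with non-zero coefficients form the
sparse spatial filter; each column is applied to the trial filtered in the
column's own originating band (the columns are only meaningful there), rows
stacked in selection order.

## Filter-bank GAN

One unconditional generator + two discriminators per (subject, class). The
generator is FC(1600 → 256000) followed by five transposed convolutions
(kernels (3,15), (3,15), (3,5), (4,5), (1,2); strides (1,3), (1,3), (1,2),
(2,1), (1,1); batch norm and LeakyReLU(0.2) on the first four; linear
output, since z-scored EEG is signed and unbounded). The published roster
fixes these endpoints but not the reshape lattice or paddings; the package
reshapes to (128, 40, 50) and uses paddings H: (1,1,1,30,0), W: (0,1,0,0,0),
under which the width trace 50 → 162 → 496 → 995 → 999 → 1000 is exact and
the height trace reaches 22 via a symmetric crop on the fourth layer. The
full trace is unit-tested.

The raw discriminator consumes (22, 1000) through four convolutions and two
(1,6) max-pools into FC(750 → 1); the FB discriminator consumes the
(n_sel, 1000) sparsely filtered trial, collapsing rows by a stride-(4,1)
convolution followed by a row-spanning kernel of adaptive height
`Var = floor(n_sel / 4)`, then the same temporal tail into FC(750 → 1). Note
`Var` depends on n_sel only through `floor(n_sel/4)` — 16 and 17 selected
columns share `Var = 4`; 16 and 20 differ. (The fourth raw-block convolution
is implemented with stride (1,1): the published stride (1,7) is inconsistent
with the FC width 750 that the same table fixes, and the FB block's matching
layer is printed with stride (1,1).)

Losses are standard binary cross-entropies; the discriminator objective sums
both discriminators, the generator uses the non-saturating loss with weights
(w_φ, w_ψ) = (1, 1) by default. Adam (lr 1e-4, β = (0.5, 0.999)), batch 5,
1:1 update ratio, no label smoothing — all config-exposed. The number of
training epochs is not specified anywhere; it is a config field.

**Differentiable band filtering.** The FB discriminator's input requires
backpropagating through the band filters. Inside the GAN the zero-phase
Butterworth band is applied spectrally — the rFFT is multiplied by the
squared magnitude response |H(f)|² (circular convolution with a symmetric
kernel). This operator is exactly linear and self-adjoint, so its backward
pass is the operator itself; it differs from `sosfiltfilt` only in edge
handling. Preprocessing proper keeps `sosfiltfilt`.

**Data source under LOSO.** The GAN trains on the held-out target subject's
own trials (that is the published protocol; whether it leaks information
into the LOSO test is a genuine open question). The package's evaluation
helpers use the target's *first session* for GAN and sparse-filter fitting,
the conservative reading.

## CRNN-DF classifier

Input (1, C, T) → Conv(C × 45, stride 1, 64 filters, ReLU) →
MaxPool(1 × 75, stride 10) → dropout 0.5 → 2-layer LSTM (hidden 64, dropout
0.5 between layers) → dropout → linear head. The sequence length after
conv/pool is `floor(((T−45+1)−75)/10)+1` (89 at T = 1000). The feature
vector `v` for the center loss is the final hidden state of the last
recurrent layer (64-d) — the representation the classifier head actually
sees. The convolutional filter count (64) and activation are open choices
(the published figure is unreadable); both are config fields.

The discriminative-feature objective adds `λ · L_cen` with
`L_cen = (1/b) Σ ‖v_i − cen_{y_i}‖²` (squared Euclidean — the center-loss
convention, differentiable at zero), λ = 0.1. Centers are initialized from
the whole training set with the shrunken mean `Σδ(y_i=j)v_i / (1 + Σδ(y_i=j))`
— the "+1" is implemented as printed (an empty class maps to the zero
vector); a plain-mean switch exists. Every 15 epochs centers are
re-estimated as (shrunken) class means of the *current* features — centers
must track feature drift for the loss to stay meaningful — and then moved a
step α = 0.02 along the unit vector from the global center mean toward
themselves; a center coincident with that mean does not move. Centers are
schedule-updated only, never gradient-trained. Classifier optimizer: Adam
(lr 1e-4, β = (0.9, 0.999)), batch 32, 200 epochs by default.

## LOSO evaluation and augmentation

`loso_split` pools every trial of every non-target subject (all sessions)
into a seeded shuffled training set; the target's trials form the test set
(9 × 2 × 288 trials → 4608/576). `augment` appends `n_aug/4` generated
trials per class to the training set only (3000 → 750 per class) and
reshuffles. Every trial carries a (subject, session, index, synthetic)
identifier and `leakage_audit` verifies that no real identifier crosses the
split and every synthetic trial belongs to the target. Mean/std across
subjects use the arithmetic mean and population std. Generated-data quality
is reported as class-average channel traces (C3/Cz/C4 by default), the
trial-averaged spectrogram of the channel-mean signal (1–38 Hz, dB), and
trial-averaged unit-diagonal channel covariance matrices compared by the
Pearson correlation of their strictly-upper triangles.

## Synthetic data

A trial is `background + amp · a_c s(t)`: `s(t)` is unit-RMS narrowband
noise in the class's rhythm band, `a_c` a unit spatial pattern concentrated
on a small sensor neighborhood (four disjoint neighborhoods by default,
rhythms at 8–12 and 16–24 Hz), and the background mixes 1/f (pink) and white
noise (70/30) so the filter bank is exercised non-trivially. `snr` is
density-based: at the most-loaded channel the in-band PSD elevation is
`snr²` relative to a 4-Hz reference band, independent of the rhythm's
bandwidth — so for any `snr ≥ 1` the class-mean PSD peaks inside the class
band rather than on the 1/f shoulder. Subjects differ by a random pattern
perturbation (`subject_shift_sd`) and a log-normal gain, shared across their
sessions; this produces the cross-subject transfer gap the pipeline
addresses. Everything is a pure function of the config, including its seed.

What the generator does **not** emulate: volume conduction from dipolar
sources, artifacts (EOG/EMG), non-stationarity within a session, and
realistic channel covariance of the background. Passing the synthetic
benchmarks therefore establishes that the implementation is correct and the
mechanisms behave as designed — not that the paper-scale accuracies on real
recordings are reproduced.

## Scaled benchmark configurations

Full-scale training (22 × 1000 trials, thousands of epochs per subject and
class) is far beyond a desk run, so the reference experiments in
`mieeg.experiments` use reduced problem sizes, chosen once:

* **Classifier study:** 8 channels, 64 Hz, 4-s trials, 20 trials/class,
  snr 1 (a realistic band-power effect size), full-size classifier roster;
  lr 1e-3, 90 epochs (six center-update cycles — long enough for the center
  loss to keep contracting clusters after the classification loss
  saturates). Reported: training accuracy and the within/between-class mean
  pairwise feature-distance ratio for λ = 0.1 vs λ = 0, paired by seed.
* **GAN covariance study:** a planted rank-2 (+ ridge) channel covariance,
  8 channels × 64 samples, 60 trials; the `small` generator/discriminator
  variants (same layer types, three ×2 upsampling stages); the FB
  discriminator's sparse filter is the top-4 eigenvector basis of the
  planted covariance (a synthetic stand-in for a CSP-derived filter on this
  single-class fixture). Reported: Pearson correlation between real and
  generated normalized channel covariances.
* **Augmentation benchmark:** 3 subjects × 2 sessions × 10 trials/class,
  subject shift 0.8 (a pronounced cross-subject gap), sparse-CSP and
  per-class GANs fitted on the target's first session, 10 generated trials
  per class mixed into the pooled training set. Reported: LOSO accuracy
  with and without augmentation, three seeds.

## Numerical choices and limitations

* All networks run in float32 on the hand-written numpy layer library;
  every layer's backward pass is verified against central finite
  differences in float64 in the test suite.
* `Conv2d` materializes an im2col matrix (bounded by batch × positions ×
  patch); `ConvTranspose2d` instead loops one `tensordot` per kernel offset,
  keeping memory at activation size for the 256000-wide generator.
* Zero-variance CSP projections are floored at 1e-30 before the log.
* LASSO solutions use tolerance 1e-8 (fixed λ) so KKT conditions hold to
  ~1e-6.
* The LASSO on numeric labels can select zero columns for large λ; this is
  reported as an error advising a smaller penalty rather than silently
  returning an empty filter.
* GAN training is adversarial and small-batch; histories are seeded and
  reproducible, but equilibrium is not guaranteed at any fixed budget. The
  scaled studies use budgets at which covariance recovery is robust across
  seeds.
* The full-size generator holds a 1600 × 256000 dense layer (~410 M
  parameters); building it and running a forward pass is tested, but
  training at that width is only sensible with the documented `small`
  variants on desk hardware.
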