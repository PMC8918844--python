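# Methods

## The model

A *class knowledge bank* (CKB) replaces the usual linear classification
head.  For an `N`-class problem, class `i` owns a bank
`C_i = {u_i1, …, u_iM}` of `M` trainable *knowledge units*, each a
`D`-dimensional vector.  An input `x` is embedded by an encoder and a
projection head,

    r0 = Encoder(x),    r = Projection(r0),    r ∈ R^D,

and the logit of class `i` is the mean cosine similarity between `r` and
the class's units:

    s_i = (1/M) Σ_j cos(u_ij, r),    cos(u, r) = u·r / (‖u‖‖r‖).

Class probabilities are `p_i = softmax(s)_i`.  Training minimizes, per
sample with label `y`,

    L = L_con + L_cel,
    L_con = −s_y + (1/(N−1)) Σ_{i≠y} s_i,
    L_cel = −log p_y,

i.e. a contrastive pull toward the correct bank and push away from the
mean of the others, plus ordinary cross-entropy on the similarity
logits.  A batch contributes the unweighted mean of its per-sample
losses.

Two structural consequences follow from logits being means of cosines
and are enforced as invariants throughout the package:

* `s_i ∈ [−1, 1]`, hence `L_con ∈ [−2, 2]` with `−2` attained exactly in
  the two-class perfect-separation configuration, and
  `max_i p_i ≤ e² / (e² + N − 1)` — the head can never be arbitrarily
  confident;
* all outputs are invariant under positive rescaling of any unit or of
  `r`, and under permutation of units within a class.

Because every class owns the same number of units and `L_con` weighs the
correct class and the average wrong class equally regardless of how
often each class appears, the head has no structural incentive to favor
the majority class.  The imbalance experiment below measures exactly
this.

## Implementation and gradients

The whole stack — linear layers, batch normalization, ReLU, a small 3×3
convolutional encoder, AdamW, and the bank head — is implemented
directly in NumPy with hand-derived analytic gradients.  For the bank
head, with `û = u/‖u‖`, `r̂ = r/‖r‖`, `c = û·r̂`:

    ∂c/∂u = (r̂ − c û) / ‖u‖,        ∂c/∂r = (û − c r̂) / ‖r‖,

and both loss terms act through the logits with
`∂L/∂s_i = (p_i − 1[i=y]) + (−1[i=y] + (1 − 1[i=y])/(N−1))`.
A dedicated test validates every analytic gradient (all bank units and
`r`) against central finite differences with step `1e−4` at relative
tolerance `1e−3`; a separate spot-check does the same through the
convolutional encoder.  All forward formulas are additionally checked
against independent brute-force double-loop oracles at `1e−6` on more
than a hundred random instances.

Degenerate inputs are rejected loudly: a zero-norm vector fed to any
cosine raises an explicit error rather than propagating NaN or a silent
zero, because a silently zeroed similarity would corrupt training
invisibly.

## Architecture choices

* **Projection head** — three linear layers; batch normalization and
  ReLU after the first two, batch normalization alone after the last.
  The normalization layers carry learnable scale/shift.  Evaluation mode
  uses running statistics (momentum 0.1) so single-sample inference is
  well defined; requesting evaluation before any statistics exist is an
  error, not a guess.  A `bypass` flag turns the head into the identity
  map — a test affordance that lets the banks act on raw features, used
  by the Bayes-recovery experiment and nothing else.
* **Encoders** — `identity` for feature vectors, and `tiny_conv` for
  images: three blocks of 3×3 convolution + ReLU + 2× average pooling,
  then global average pooling to `D0` channels.  It is the smallest
  encoder that separates the synthetic image classes; by default it is
  frozen at its random initialization and only the projection head and
  the banks train, mirroring the frozen-pretrained-encoder regime the
  recipe assumes.  When the encoder is frozen its outputs are computed
  once and cached.
* **Bank initialization** — i.i.d. standard normal units rescaled to
  unit norm.  The scale is irrelevant to every forward value (cosine),
  but unit norm equalizes the initial gradient magnitude across units.
  Units are *not* re-normalized during training.
* **Prediction ties** break to the lowest class index,
  deterministically.  `N = 2` uses the general `N`-class formulas; there
  is no special binary path.

## Training recipe

Defaults in `TrainingConfig` follow a standard transfer-learning recipe
for this problem class: AdamW (decoupled weight decay), learning rate
`5e−4`, weight decay `0.01` applied to weight matrices and bank units
but not to biases or normalization scale/shift, a step schedule
`lr(e) = lr0 · 0.6^⌊e/2⌋` counting epochs, batch size 64, 20 epochs,
`M = 64` units per bank.  `D` is configurable with default 512 (the
width of the three-layer comparison classifiers); desk-scale experiments
use 8–32.  Data order is reshuffled every epoch from the run seed; the
last incomplete batch is kept; there is no gradient clipping, early
stopping or validation-based selection.  Identical `(data, config,
seed)` produce bit-identical parameters — the loop is single-process
NumPy with no hidden nondeterminism.

The packaged experiments (Bayes recovery, image runs, imbalance
comparison, cross-validation) pass `learning_rate = 5e−3` explicitly.
The default rate is tuned for corpora of ~10⁴ augmented image patches —
hundreds of optimizer steps per epoch; the desk-scale sets here provide
only tens of steps per epoch, far too few at `5e−4` for the banks to
rotate from random initialization to their class directions.  One
contract test (both heads on a perfectly separable imbalanced set) uses
`1e−2` for the same reason: the cross-entropy baseline fits the minority
class slowly.  All other recipe constants are used as given.

## Synthetic data

* **Gaussian feature clusters.** Labels from configurable class priors;
  features from isotropic Gaussians at per-class means with common
  dispersion `σ`.  Default mean separation `δ = 4σ`.  Isotropy makes the
  two-class equal-prior Bayes error exact — `Φ(−δ/(2σ))` — so the
  end-to-end claim is anchored to a closed form: at `δ/σ = 4` the
  trained bank head's held-out error must land within 0.05 of
  `Φ(−2) ≈ 0.0228` (it typically lands within 0.005).
* **Images.** 32×32 RGB by default: a textured skin-toned background
  with a soft-edged central blob whose hue/saturation/granularity depend
  on the label — yellowish and granular for the positive class, pale and
  smooth for the negative — echoing the qualitative visual cues of
  wound photographs (secretion color, dryness) without claiming clinical
  realism.  `cue_strength` interpolates the class-specific appearance
  toward a shared neutral appearance; at 0 the two classes are
  *identically distributed*, giving an exact null for the no-signal
  check.
* **Prior presets.** `balanced` (1:1), `infection` (628:831, mild
  imbalance) and `ischaemia` (1,249:210, ≈6:1) — sample-count ratios
  representative of real wound-classification corpora.

What the generators do *not* emulate: encoder pretraining effects,
patch-level augmentation correlations, lighting/scale variation, and
inter-image dependence.  Passing tests therefore certify the method's
formulas, optimization and imbalance behavior — not clinical
performance on real ulcer images.

## Experiments the package ships

* **Bayes recovery** (features, identity encoder, projection bypass,
  `D = 8`, `M = 4`, 2,000 train / 4,000 test): held-out error within
  0.05 of the closed-form optimum and accuracy ≥ 0.95.
* **Image pipeline** (`tiny_conv` frozen, 600 train / 200 test, 32×32):
  held-out accuracy ≥ 0.9 at `cue_strength = 1`; at `cue_strength = 0`,
  mean accuracy over 5 seeds within 3 binomial standard deviations of
  the 0.5 prior.
* **Imbalance comparison** (ischaemia priors, `δ/σ = 2` moderate
  overlap, 1,459 train / 1,459 test per seed, 11 matched seeds): the
  bank head and a linear + cross-entropy head train on identical data;
  the median |sensitivity − specificity| of the bank head must not
  exceed the linear head's.  Observed medians are ≈0.02 (bank) vs
  ≈0.4 (linear): the linear head buys specificity by sacrificing
  minority sensitivity, the bank head does not.
* **Protocol fidelity**: schedule law exact, frozen encoder bit-identical
  across training, same-seed runs bit-identical, stratified 5-fold
  cross-validation reproducible with the aggregate equal to the fold
  mean.

Problem sizes were chosen so the entire suite and the acceptance script
each run in minutes on one CPU core while keeping every statistical
check comfortably powered.

## Numerical notes and limitations

* Cosines are clipped to `[−1, 1]` after computation to absorb rounding
  at the boundary; losses and gradients use the unclipped values.
* Batch normalization with a single-sample batch degenerates to the
  `ε`-guard (`ε = 1e−5`); training batches should be ≥ 2.
* Stratified folds are used for cross-validation (plain folds could
  lack minority positives at 6:1 imbalance); the positive class is
  index 1 by convention and configurable.
* AUC scores use the positive-class probability; since softmax is
  monotone in `s_1 − s_0` for binary tasks, logit differences would give
  the identical ranking.
* The checkpoint bundle (`.npz` + embedded JSON metadata) restores every
  parameter, the normalization running statistics and the specs
  bit-exactly; a version tag guards format drift.
* For real image manifests, fold splitting happens at the manifest-row
  level; if rows are augmented patches of shared source images, fold
  leakage is possible — a property of the manifest, not of the method.
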