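# Methods

## Overview

`duofuse` implements a two-stage fusion cascade for texture-driven image
classification. Stage 1 operates on *feature blocks* — the n × d matrix one
extraction method produces over a dataset — and decides which blocks to fuse;
stage 2 operates on classifier decisions. The package's contribution is the
cascade itself; the surrounding steps (descriptor computation, classifier
fits, file formats) go through scikit-image, PyWavelets, scikit-learn, h5py
and pandas.

## Data handling

A dataset is a manifest of (image path, class label, patient id,
magnification). Splitting is always **patient-disjoint**: patients are
sorted, shuffled by the seed, and round-half-up(train_fraction × #patients)
patients are assigned to training, every image following its patient. This
prevents identity leakage, which inflates image-level splits on histology
data. Default train fraction 0.7.

Augmentation expands each source image into `factor` variants (default 30,
chosen so that published per-magnification dataset sizes are integer
multiples of the source counts). Transforms and default ranges: rotation
±30°, shear ±10°, zoom 0.9–1.1, shift ±10% of the side, horizontal/vertical
flips at probability 0.5, centre crop retaining 90–100% then resize. The
sources name the transform families but not their magnitudes; these ranges
are conventional for texture imagery. Variant parameters are drawn from a
per-record seeded stream, and rendering is lazy, so count-level reasoning is
free of pixel work. Augmentation applies to both pools by default (matching
the published protocol, which augments after the person-level split) with a
train-only option, since augmenting test data is unconventional.

## Feature extraction

**HOG** (five stages: global gamma normalization, first-order gradients,
magnitude-weighted orientation histograms per 8×8-px cell, L2 block
normalization over overlapping 2×2-cell blocks at one-cell stride,
flattening) is computed by scikit-image on the luminance channel
(0.299/0.587/0.114 weights) of the image resized to 64×64. The defaults were
chosen so the native length is exactly 2,156 = 7×7 blocks × 4 cells × 11
unsigned bins — the canonical width — since only the total dimensionality is
published. Signed (0–360°) bins and non-unit block strides are config fields
that currently raise: scikit-image computes unsigned orientations at unit
stride, and nothing in the cascade needs the variants.

**WPD** expands the full wavelet-packet tree (every subband re-filtered by
the low/high-pass pair and dyadically downsampled, both axes) to level 4 and
returns all 4⁴ = 256 terminal subbands flattened in natural (Paley) order,
via PyWavelets. Default wavelet Haar, boundary mode periodization: with an
orthogonal filter pair this makes the transform an isometry, so terminal
coefficient count equals H×W and energy is conserved — both are tested to
1e-8 relative tolerance, and a hand-coded recursive-filtering oracle checks
the 1-D transform. The "best basis" entropy criterion is vacuous here
because all level-4 coefficients are taken, so the tree is always fully
expanded. A 64×64 input gives a native width of 4,096.

**Deep blocks** go through the `DeepBackend` contract: anything mapping a
preprocessed image (resized to the backend's input size — 227×227 for
AlexNet, 224×224 for GoogleNet/ResNet-50/ShuffleNet, 229×229 for
Inception-ResNet V2) to a fixed-length vector, deterministically for fixed
parameters. Pretrained backbones are optional plugins; the shipped
**filter-bank backend** (seeded zero-mean random 7×7 convolutions, ReLU,
average pooling over a grid; declared_dim = n_filters × grid cells) is a
weight-free deep-feature stand-in that is deterministic, sensitive to every
pixel, and discriminative on oriented textures.

**Canonical widths.** The published block widths (Inception-ResNet V2 7,852;
ResNet-50 5,000; ShuffleNet 6,034; AlexNet 3,520; GoogleNet 4,600; HOG
2,156; WPD 1,067) make the fused-width arithmetic meaningful (e.g. the
five-block forward winner is 23,128 columns; all seven blocks 30,229), but
none of the deep widths matches the standard architectures' pooling outputs
and the WPD width is not derivable from the stated transform. A
`DimensionAdapter` (truncate, zero-pad, or a seed-fixed random projection
with orthonormal rows/columns) maps native widths onto the canonical ones;
it is an explicit reconciliation device, not a claim about how the original
widths arose.

## Stage 1: ranking, greedy search, autoencoder fusion

The **evaluator** scores a feature matrix by training a classifier
(default SVM; RF, QDA and a best-of-three mode are selectable) on the
training rows and measuring accuracy on the held-out patients. Blocks are
ranked descending by individual accuracy, ties broken by name for
determinism.

**Forward search** starts from the top-ranked block and tries the remaining
blocks in rank order; **backward search** starts from all blocks and tries
removals from the lowest rank upward. In both, a change stands only on
*strict* improvement — equal accuracy rejects it — which biases toward
smaller sets and makes trajectories deterministic. Candidate sets are cached
by their unordered name set so identical sets are scored once. Trajectory
entries carry FS-k-\<tag\>-\<FW|BW\> identifiers, where FS-1 is the starting
set and FS-k the candidate at trial k−1 (in backward mode, k−1 removal
trials completed). The search uses the raw concatenation by default; an
option applies the autoencoder inside the search loop, at substantially
higher cost.

The selected blocks are concatenated (width = Σ component widths) and
reduced by a **single-hidden-layer autoencoder**: per-column min-max scaling
to [0,1] (learned on training rows), a sigmoid (or linear) encoder to the
bottleneck, a symmetric decoder, minimizing mean squared reconstruction
error by minibatch SGD with momentum. The default bottleneck is
round(0.3 × D), matching the published after/before width ratios
(0.26–0.32). Two hyperparameter profiles: **published** (epochs 20, learning
rate 0.045, momentum 0.9, weight decay 0.9 — kept as published, though an
L2 coefficient of 0.9 is unusually large and shrinks weights aggressively)
and **practical** (weight decay 1e-4). Numerical choices: Glorot-uniform
initialization from the config seed; the loss gradient is averaged over
samples and summed over features so the step size is independent of the
input width; the returned parameters are those of the best epoch by
full-batch loss, which guarantees the recorded final loss never exceeds the
initial one; constant columns scale to zero rather than dividing by zero.
With a full-width bottleneck and linear activations (an explicit test mode)
the model is identity-capable and training drives reconstruction MSE below
1e-3. The synthetic pipeline default uses the practical profile at 100
epochs: at 20 epochs the reconstruction is still poor enough to destroy the
blocks' class information, which defeats the purpose of the fusion.

## Stage 2: majority-voting ensemble

Three members — SVC (RBF kernel), RandomForest (100 trees), QDA
(regularization 1e-4) — are trained on identical rows, each behind a
standardization step. Member hyperparameters are deliberately conventional:
the contribution under study is the fusion scheme, not member tuning. QDA is
guarded by a PCA projection whenever some class has no more samples than
features, where the class covariance would be singular beyond what the
regularizer absorbs. Per-member validation accuracy is recorded on a seeded
stratified hold-out (or a supplied validation set) before refitting on all
rows. Prediction takes the per-sample modal label; with three members and
binary labels no tie is possible (pigeonhole); multiclass three-way ties go
to the member with the highest validation accuracy (default) or to the first
member. Voting is on hard labels, not probabilities.

## Evaluation

Confusion counts designate **benign as the positive class** (the published
convention; most CADx literature designates malignant — the positive label
is a parameter). The five measures follow the standard confusion-ratio
definitions; a zero denominator yields `None`, a distinct undefined marker,
never a silent 0 or 1, and macro (one-vs-rest, unweighted) averages exclude
undefined per-class values with a warning. A positive label absent from both
vectors is legal and simply yields zero positive counts.

## Synthetic data: what it emulates and what it does not

*Texture images* are band-pass filtered Gaussian noise with an oriented
annular passband; the class signal lives in the dominant spatial frequency
(step 0.03 cycles/px per class) and orientation dispersion (step 0.15 rad),
both scaled by an `effect_size` knob; a per-patient intensity offset (SD
0.05) makes patient-disjoint splitting consequential. At effect size 0 the
class-conditional distributions are identical (verified by KS calibration);
at effect size 3 HOG features support >0.9 patient-disjoint accuracy.
*Feature blocks* are class-conditional Gaussians with unit within-class
variance; informative coordinates separate class means by a configurable
number of within-class SDs, so the two-class single-coordinate Bayes
accuracy is Φ(separation/2) in closed form.

These generators reproduce the *structure* the cascade exploits —
block-level differences in discriminability, redundant and pure-noise
blocks, patient grouping — but not the appearance of histology: no nuclei,
glands, stain variation, or magnification-dependent morphology. Passing
tests therefore demonstrate the correctness and the qualitative behaviour
of the machinery (noise exclusion, fusion gains, vote behaviour), not
clinical-grade accuracy on real slides.

The default synthetic study used by the pipeline and the verification suite:
five blocks (separations 1.5/1.0/0.8 on 5 informative coordinates each, two
pure-noise blocks), 300 samples, 2 classes, 6 synthetic patients per class,
70/30 split. The planted-noise recovery fixture gives the pure-noise block
width 200 against dim-10 informative blocks (n = 400, separation 0.8), mirroring the order-of-magnitude
width disparity between deep and handcrafted blocks in the real system —
a narrow noise block is harmless to an SVM and the strict-improvement rule
correctly declines to remove it. Problem sizes throughout (n = 200–600,
block widths 8–100, 5–20 seeds per Monte-Carlo property) were chosen as the
smallest at which the distributional properties under test are stable.

## Known limitations

- The five published deep widths are adopted via the dimension adapter, not
  derived from the named layers; results on real backbones depend on the
  plugged-in weights.
- Whether the published protocol scores augmented test sets per patch or per
  source image is unstated; the package evaluates per record and leaves
  aggregation to the caller.
- The greedy searches are sequential (no floating variants) and evaluate
  whole blocks, never individual features.
- The autoencoder has exactly one hidden layer; deeper stacks are out of
  scope.
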