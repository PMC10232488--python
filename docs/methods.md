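# Methods

## Problem setting

The package classifies fixed-size H&E-stained tissue tiles into K tissue
classes (K ≥ 2).  Input datasets are directory trees with one folder per
class; splits are a single stratified 60-20-20 hold-out (train /
validation / test), not k-fold cross-validation.  Per class of size n the
validation and test splits take `round(0.2·n)` tiles (round half away
from zero) and train absorbs the remainder, so counts are exact and no
tile is dropped or duplicated.  This rounding reproduces the published
data-setting tables of the two public colorectal tile collections for
every self-consistent row (e.g. a class of 10,446 tiles splits
6268/2089/2089); a few published rows are internally inconsistent with
their own totals and are treated as typos.

## Preprocessing

Tiles are converted to HSV with the standard hexcone formulas.  Hue is
stored on [0, 1) rather than degrees so all three network channels share
one range; achromatic pixels get hue 0 by convention.  All three channels
are fed to the network — HSV is used to decouple chroma from staining
intensity, not to drop information.  Hue's circular discontinuity is left
as-is (no sin/cos encoding).  Resizing is bilinear, channels-first, with
values clipped to [0, 1].

## Feature extractor

A residual backbone: stem 3×3 convolution (stride 2), then stages of
blocks `conv3×3 → BN → ReLU → conv3×3 → BN` with an additive shortcut
(1×1 projection + BN when shape changes) and a final ReLU.  Presets:

- `reduced` (default, used throughout the tests): 3 stages of 1 block at
  16/32/64 channels — trainable on one CPU in minutes.
- `resnet50-like` / `resnet101-like`: 4 stages of 3/4/6/3 and 3/4/23/3
  blocks at 64–512 channels, for paper-scale runs.

Each of the last three stage outputs passes through a DiConv-attention
block: three parallel dilated 3×3 convolutions with rates (1, 2, 3) by
default (rates are configurable; (1, 2, 5) is also plausible from the
source material and supported), fused as `Output = Σ µ_i D_i`.  The
branch weights are computed as `A_i = GAP(D_i)`,
`η_i = sigmoid(dense1(A_i))`, `raw_i = dense2(η_i)` and
`µ = softmax(raw_1..raw_3)`.  Putting the softmax last guarantees
Σ µ_i = 1, which the additive fusion needs in order to preserve scale;
µ_i is a per-branch scalar, not per-channel.  The two dense layers are
shared across branches by default (configurable), which makes identical
branches provably receive uniform weights.  The three fused maps are
bilinearly upsampled to the earliest tapped stage's resolution,
concatenated, projected by a 1×1 convolution to `feature_dim` (default
64) channels, batch-normalized, ReLU'd and global-average-pooled into the
feature vector.  A detachable softmax head is used only to train the
backbone.

The insertion point of the attention block (after the last three stages,
upsample → fuse → concatenate) and the uniform-range HSV input scaling
are design choices of this package; the source material motivates the
components but does not fix either.

All layers are NumPy with hand-written backprop (im2col convolutions,
standard batch-norm gradients, interpolation-matrix bilinear resize).
Correctness is established by exhaustive small-instance equivalence with
loop oracles and by central finite differences on every layer and on the
composed network.  Object-detection vocabulary that sometimes accompanies
multi-scale feature pyramids (anchor boxes per grid cell) has no meaning
for tile classification and is not implemented.

Training: Adam, learning rate 0.002 (the published setting), batch 64,
early stopping on validation loss with configurable patience,
best-validation weights restored.  The published epoch range (500–2000)
is the paper-scale default for `TrainConfig.max_epochs`; the desk-scale
preset (`desk_scale_config`) uses 25 epochs with patience 4, which is
where the synthetic benchmark saturates.  Batch norm uses running
statistics at inference; seeds fix initialization and data order, so
training is bit-reproducible.  A pretrained stem is accepted in the
configuration surface but no weights ship with the package; tests train
from scratch.

## NCA feature selection

Weights maximize `F(w) = (1/n) Σ_i Σ_{j: y_j = y_i} p_ij − λ Σ_r w_r²`
with `p_ij ∝ exp(−d_w(x_i, x_j)/σ)`, `p_ii = 0`, and per-feature weighted
L1 distances `d_w = Σ_r w_r² |x_ir − x_jr|`.  Features are standardized
internally, hence σ = 1 by default; λ defaults to 1/n; gradient ascent
starts from all-ones weights with a backtracking (step-halving) line
search, weights floored at zero, 200 iterations by default (60 inside the
pipeline).  The squared-weight parameterization plus flooring enforce the
nonnegativity that makes the weights usable as a feature ranking; only
the diagonal weighting is learned, not a full linear transform.  The
pairwise |Δ| tensor is O(n²·d) memory, so the pipeline fits NCA on a
stratified subsample of at most `nca_max_rows` (default 800) training
rows.  An optional blockwise mode fits NCA independently on overlapping
feature blocks (defaults: block size 2k, stride k) and averages the
weights of features shared between blocks; this reconstruction is the
package's reading of an ambiguous description of "overlapping blocks" in
the source material.  Selection keeps the k = 50 largest weights, ties
broken by ascending index.

## DeepSVM

Every unit is a soft-margin RBF-kernel SVM solved in the dual (via
scikit-learn's SMO); the kernel is `exp(−‖x−y‖²/c)` with width c
defaulting to the current representation's feature count, box constraint
C = 10.  The decision function `Σ_j α_j y_j K(x, x_j) + b` is evaluated
by this package's own code from the stored support vectors (sgn(0) = +1
for determinism) and is cross-checked against the library's decision
values in the tests.

The ensemble is grown layer-wise.  Depth 1 is the output layer alone — a
flat one-vs-rest multi-class SVM on the input features.  Each further
depth inserts a hidden layer of K one-vs-rest units (each optionally
trained on a seeded bootstrap resample when bagging is enabled),
transforms train and validation sets to the units' decision scores
(concatenated with the layer input when pass-through is on, the default —
raw scores preserve margin information and the skip prevents
representation collapse at small K), refits the output layer, and records
validation accuracy.  Construction stops after `patience` (default 2)
consecutive non-improving depths and the model is truncated at the
best-validation depth.  Because depth 1 is always a candidate and the
returned depth attains the per-depth maximum, the ensemble's validation
accuracy is ≥ the flat SVM's by construction.  The layer-wise recipe is a
reconstruction from a figure-level description; the published learning
rate/epoch settings cannot govern a dual SVM solve and are applied to the
backbone stage only.

## Synthetic data

The generator emulates the statistical skeleton of the real tile
collections: K classes (default 8) of color textures, each combining a
class-specific base hue (evenly spaced on the hue circle), a
class-specific periodic pattern (stripes, checks, smoothed-noise blobs or
speckle, with class-specific frequency and orientation), and additive
Gaussian pixel noise (`noise_sd`, default 8 on the 0–255 scale).  The
last class is near-uniform bright and almost unsaturated, emulating the
background/empty-slide class both real datasets contain.  All randomness
derives from `(seed, class_id, draw_index)`, so tiles are individually
reproducible and no global random state is consumed.

What it does *not* emulate: nuclei and gland morphology, stain variation
between slides, focus blur, tiles straddling two tissue types.  Passing
the synthetic benchmark therefore shows the pipeline's machinery is
correct and end-to-end trainable, not that real-data headline accuracies
transfer; runs on the real Zenodo datasets use the same code path but
paper-scale presets and are out of the test budget by design.  Benchmark
problem sizes used by the tests and the acceptance script — 8 classes ×
200 tiles at 64×64 with the reduced backbone — were chosen so a full run
completes in a few CPU-minutes.

## Numerical choices and degenerate inputs

- Convolutions are cross-correlations (no kernel flip), zero "same"
  padding, odd kernels only; even kernels with "same" padding are a
  configuration error.
- Bilinear resize uses half-pixel-center interpolation matrices that are
  row-stochastic, so constants are preserved exactly.
- Batch-norm eps 1e-5, momentum 0.1; batches of size 1 are skipped during
  training.
- NCA line search accepts a step if the objective does not decrease by
  more than 1e-12, halving up to 25 times; the trace is therefore
  non-decreasing up to that tolerance.
- Confusion-matrix precision for a class never predicted is defined as 0
  with a logged warning; an all-zero matrix is an error.
- Grayscale tiles are replicated to three channels with a warning;
  undecodable files are skipped at scan time (warning) but are an error
  at load time.

## Known limitations

- The NumPy engine is CPU-only and single-threaded beyond BLAS; the
  paper-scale presets are provided but take hours, not minutes.
- NCA cost is quadratic in rows; the subsampling default trades a little
  weight stability for tractability.
- DeepSVM stores every layer's support vectors; at 10⁵-tile scale the
  model artifact grows accordingly.
- No stain normalization or WSI-level aggregation; only pre-cut tiles.
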