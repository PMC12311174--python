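# Methods

## Problem setting and model

A whole-slide image carries only a slide-level label (fusion present or
absent); which tissue regions express the fusion-associated morphology is
unknown. We treat the slide as a bag of tile feature vectors and learn a
bag-level classifier whose attention mechanism locates the informative
tiles. The pipeline has two learned stages — a self-supervised tile
encoder and a supervised transformer aggregator — plus deterministic
preprocessing and evaluation stages around them.

### Tissue mask chain

Masking runs at thumbnail resolution and refines one shared binary mask
in sequence; every stage only removes pixels except hole-filling, and the
per-stage signed pixel deltas are recorded in `stage_log`:

1. **Blur rejection.** Grayscale |Laplacian|, Gaussian-smoothed with
   σ = 2 px; a pixel survives if the smoothed edge energy is ≥ 0.05 of the
   intensity range. Blurred patches and flat background both fail this.
2. **Flat-background rejection.** Local mean absolute deviation from the
   15-px window mean; pixels below 0.04 of the range are dropped.
3. **Morphology.** Connected components below 64 px are removed
   (components of exactly the threshold size are kept); enclosed holes
   smaller than 64 px are filled.
4. **Fat and dark-label excision.** Connected near-white regions
   (gray > 0.85) that do not touch the image border and have ≥ 8 px are
   removed (enclosed fat); components whose *median* intensity is < 0.30
   with rectangularity (area / bounding-box area) > 0.60 are removed
   (printed labels). The median rather than the mean is used for darkness
   because the edge filters keep a thin bright halo around a label which
   would otherwise drag the component mean above any sensible cutoff.

No published numeric thresholds exist for these stages; all values above
are package defaults exposed in the mask config, calibrated once on the
synthetic slide generator and not claims of fidelity to any scanner.

Tiling emits non-overlapping, grid-aligned 224 × 224 footprints
(half-open, 0-based, x right / y down) whose mask coverage is
≥ `coverage_min` (default 0.5, the midpoint; the paperless choice that
avoids edge-tile noise). Coverage is computed exactly for fractional
thumbnail footprints by bilinear interpolation of the mask integral
image, which is exact for piecewise-constant masks. Working magnification
is treated as a resolution parameter: images are assumed supplied at
working resolution or rescaled by their metadata factor; scanner pyramid
handling is out of scope.

### Tile encoder

Momentum contrast with a ViT backbone: query encoder updated by Adam, key
encoder by EMA with momentum m (default 0.99); two augmented views
(random resized crop, flips, brightness/contrast jitter) of each tile
form a positive pair and the other keys in the batch are negatives;
InfoNCE at temperature τ = 0.2. The query side adds a two-layer
projection and prediction head; keys use projection only; features for
downstream bags are the raw backbone outputs (unnormalized, d = 384 by
default). In-batch negatives are used rather than a memory queue. The
reference hyperparameters for this family of models are not published for
the motivating study, so m, τ, learning rate and batch size are config
with the stated defaults. Tests use a tiny backbone (32-px tiles, patch
8, one layer) where instance discrimination is learnable in ~50 steps.

### Aggregator

Projection d_in → d_model (default 384 → 512), learned CLS token, two
pre-norm transformer encoder layers with 8 heads, MLP head (one hidden
layer of width d_model, ReLU) on the final CLS embedding. No positional
encodings: a bag is an unordered set, and the slide logit is permutation
invariant (verified to < 1e-4 over 100 permutations). Duplicating every
tile is *approximately* invariant: the CLS key's softmax mass halves, an
O(1/n_tiles) effect inherent to any CLS-token transformer. Per-tile
classification scores use the singleton-bag pathway — tile i's score is
the model's output on the bag {i} — chosen over bypassing the transformer
because it reuses the exact trained forward path.

### Cohorts and training

RAN = ROS1 ∨ ALK ∨ NTRK. A 15% holdout is carved first (uniform random;
the motivating cohort's holdout was described only as random sampling);
the remainder forms the CV set, split into k = 5 *independent* stratified
60/20/20 train/val/test draws (largest-remainder rounding per class, so
counts match the fractions to within one sample). Training negatives are
downsampled once per fold to 5 : 1 against positives; validation and test
sets are untouched. The loss weights the positive class by W (default 5)
in both training stages. Fine-tuning starts from the RAN checkpoint with
the best RAN validation AUC (checkpoint selection by validation argmax,
earliest on ties; whether the original procedure selected or took the
last step is unstated — selection is the package's choice) and runs at
lr × 0.1 on the same fold. Optimizer is Adam (lr 1e-3 default); the
decision threshold for confusion matrices is fixed at 0.5.

### Evaluation

ROC AUC is the Mann–Whitney statistic (ties ½), asserted against an
exhaustive pair-counting oracle; PR AUC uses step-wise precision
integration over distinct recall points. PPA = TP/(TP+FN),
NPA = TN/(TN+FP), PPV = TP/(TP+FP); predictions use score ≥ t with ties
positive. Trade-off curves sweep all distinct scores and report FN/n and
TN/n — rates over *all* cases, the quantities a pre-screening deployment
trades against each other. Fold aggregation uses the sample (n−1)
standard deviation; a single fold reports sd 0 with a flag.

### Interpretability

Rollout mixes each head-averaged attention matrix with the identity at
coefficient ½ and multiplies across layers; the CLS row over tile columns
is reported unnormalized (CLS self-mass excluded, no re-scaling), with
min–max scaling applied only at render time — the math and the display
are kept separate, and whether per-slide normalization is applied before
display is a presentation choice, not part of the statistic.

## Synthetic data: what it emulates and what it does not

**Slides.** Textured tissue rectangles/ellipses on a near-white noisy
background, plus the three artifact classes the mask chain must reject:
Gaussian-blurred patches (feathered at the boundary so no artificial
sharp edge marks them), near-black textured label rectangles off-tissue,
and enclosed near-white fat-like holes. Ground-truth masks per class are
returned; the "tissue" truth excludes artifact regions. Not emulated:
stain variation, pen marks, tissue folds, scanner-specific color
profiles, photorealistic texture.

**Feature bags.** Negative-bag tiles are isotropic Gaussian noise
(sd = 1). A positive bag replaces a `signal_tile_frac` (default 0.25)
fraction of tiles with noise plus a shift of
`(shared_effect·u_shared + specific_effect·u_label + heterogeneity·g)·sd`,
where u_shared and the three u_label are orthonormal directions fixed per
seed and g is a random unit direction drawn per slide. Defaults:
shared 2.0, specific 1.0, heterogeneity 2.0; prevalences 1% / 2% / 0.5%
for ROS1 / ALK / NTRK, mutually exclusive by construction (the published
cohort's label arithmetic implies no co-positive samples). The
heterogeneity term models patient-to-patient morphological variability:
it is what makes a handful of rare-target positives insufficient for
direct training while the composite label's larger positive pool still
reveals the shared direction — the mechanism behind the two-step
training benefit. Passing tests on these bags shows the pipeline
machinery behaves as designed under a controlled signal model; it does
not certify performance on real histology features.

**Thumbnails.** Biopsies are 5–8 small scattered fragments, resections
one large elliptical region, balanced classes; connected-component
counting separates them perfectly, making an oracle available for the
specimen classifier. The specimen CNN input is inverted (white → 0) so
that global average pooling aggregates tissue rather than background —
without this centering the tiny network converges impractically slowly.

## Benchmark problem sizes and numerical choices

Benchmarks run on one CPU in minutes: 800 slides with 15–40 tile bags at
d = 16, a d_model = 32 / 2-layer / 8-head aggregator, 35 training epochs
(10 for fine-tuning), batch size 4, five seeds; the specimen fixture uses
n = 200 thumbnails and 12 epochs; the mask benchmark uses ten 384×384
slides. The joint fusion category (ROS1/ALK/NTRK/negative) stratifies the
benchmark fold so every subset holds at least one positive of each rare
sub-label — with binary RAN stratification a desk-scale validation set
can end up single-class, which the training contract rejects. The weight
sweep trains on the composite label, whose larger positive count gives
the most stable desk-scale trade-off estimates.

All computation is float64. Softmax and log-sum-exp subtract the row
maximum; the training loss is evaluated on the logit via softplus;
probabilities reaching exactly 0/1 in the probability-space loss helper
are clamped at 1e-12 with a warning. Checkpoint selection ties break to
the earliest step. Empty bags are rejected by the aggregator; empty tile
sets are skipped with a warning during encoder sampling; a tile size
larger than the image yields an empty tile set, not an error.

## Known limitations

- The synthetic signal is linear in feature space; real fusion morphology
  is not, and the encoder/aggregator capacity needed on real data is
  far larger than the desk-scale defaults.
- One slide per patient is assumed; patient-level grouping across slides
  is not modeled.
- The specimen classifier's default backbone is the tiny CNN; a
  VGG-class stack can be plugged in but is not exercised by tests.
- Attention heatmaps are unnormalized masses; comparing absolute values
  across slides is not meaningful.
- Exact duplicate-tile invariance of the slide logit is impossible with a
  CLS token among the attention keys (see above); the effect decays as
  1/n_tiles.
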