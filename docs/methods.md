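# Methods

This note records the models, conventions and design choices behind the
package, in the order data flows through the pipeline.

## Image conventions

Images are loaded from `root/<class>/<view>/*.{png,jpg}` (the view level —
`upper`/`lower` beak — is optional). All descriptor inputs are square
grayscale grids produced by one canonical preprocessing step:

* grayscale = ITU-R 601 luminance, 0.299 R + 0.587 G + 0.114 B. The choice
  of weighting is immaterial to the method; fixing one makes descriptor
  outputs bit-reproducible.
* resizing = bilinear with half-pixel-center alignment and **no
  antialiasing**. Output pixel center (i, j) samples the source at
  ((i + 0.5)·H/out − 0.5, (j + 0.5)·W/out − 0.5), clamped to the grid. An
  identity resize is therefore exactly the identity, which also makes
  `to_gray_resized` idempotent on already-gray targets.

Coordinates are (x, y) with x = column and y = row, y pointing down — the
usual image convention. This fixes signs in both descriptors.

## Dataset partition

Splitting is stratified per class and seeded: `test_frac` of each class is
held out for testing, then `val_frac_of_rest` of the remainder goes to
validation (defaults 0.2 and 0.2, i.e. an 80/20 test split and an 80/20
train/validation split of the rest). Rounding is to the nearest sample with
a guarantee of at least one test and one validation member per class, so
per-class counts deviate from the exact ratios by at most one. Train,
validation and test id sets are disjoint by construction and checked.

## Augmentation

Training-set expansion uses affine maps y = ωx + b about the image center:
random horizontal flip (probability `p_flip`), rotation (uniform in
`rotation_range_deg`, default ±45°), random crop (area fraction in
`crop_frac_range`, resized back so downstream dimensions are unchanged) and
aspect-ratio rescale. Output pixels come from inverse mapping with bilinear
interpolation; coordinates outside the source are filled with 255, the
white light board the specimens are photographed on. Augmentation is only
ever applied to training images — the pipeline's augment stage reads the
split manifest and refuses everything else — and each augmented copy keeps
its source label and view.

## Circular uniform LBP

Sampling point p of P lies at (x_c + R·cos(2πp/P), y_c − R·sin(2πp/P));
the minus sign (y down) fixes the bit order of the code
LBP(x_c,y_c) = Σ_p 2^p·S(i_p − i_c), S(x) = 1 iff x ≥ 0. Choices:

* Fractional sampling coordinates are resolved by bilinear interpolation.
* The sign threshold is evaluated with an absolute tolerance of 1e-9:
  interpolating equal neighbors must compare as "equal" to the center
  (S(0) = 1), and exact equality is not representable after floating-point
  interpolation on the 0–255 scale.
* Centers closer than ⌈R⌉ to a border are skipped; no padding, so no
  invented intensities enter any code.
* Uniform-pattern binning: the P(P−1)+2 codes with ≤2 circular 0/1
  transitions get dedicated bins (assigned in increasing code order) and
  all remaining codes share one catch-all bin — P(P−1)+3 bins total, 59 at
  P = 8. The descriptor is the concatenation, in row-major cell order, of
  per-cell histograms each normalized to sum 1; `grid_n` defaults to 1
  (a single global histogram), which is what yields the 59-dimensional
  texture feature used for fusion.
* Rotation-invariant remappings (ri/riu2) and multi-scale pyramids are out
  of scope.

Grayscale-shift invariance (adding a constant to the image leaves every
code unchanged) holds exactly and is tested, as is equivalence with a
literal per-pixel double-loop implementation.

## HOG

Gradients are central differences G_x(x,y) = I(x+1,y) − I(x−1,y),
G_y(x,y) = I(x,y+1) − I(x,y−1) with edge replication at borders; magnitude
√(G_x²+G_y²); orientation from the two-argument arctangent (a
single-argument arctan of G_y/G_x cannot resolve the quadrant), folded
modulo 180° in the default unsigned mode. Votes are magnitude-weighted and
split linearly between the two nearest orientation-bin centers (centers at
(k+0.5)·180/9 degrees, circular wrap). Cells are C×C pixels; blocks of 2×2
cells slide with a 1-cell stride; each block vector is divided by
max(‖v‖₂, ε) with ε = 1e-10, so a constant image yields the zero vector
and every other block has unit norm. Intensities are scaled to [0,1]
before gradient computation; together with block normalization this makes
the descriptor invariant to positive rescaling of the input.

The geometry (9 unsigned bins, 2×2-cell blocks, 1-cell stride, L2 norm) is
the unique standard configuration that reproduces all three reference
dimensions on a 256×256 input: 8100, 1764 and 324 for C = 16, 32 and 64.

## Deep backbone

The neural network layers (im2col convolution, batch normalization with
running statistics, ReLU, max/global-average pooling, linear, softmax
cross-entropy, SGD with momentum) are implemented in NumPy inside the
package (`beakfusion/_nn.py`) with explicit forward/backward passes,
verified against finite differences. Two profiles:

* `reference50` — the 50-layer bottleneck residual network: 7×7/2 stem,
  3×3/2 max pool, stages of (3,4,6,3) bottleneck units with output widths
  (256,512,1024,2048), global average pooling. Its pooled penultimate
  vector — the input of the fully connected classification layer — is the
  2048-dimensional deep feature used in fusion (only this interpretation
  matches the fused dimensions 2107 and 3812).
* `desk_small` — a 5-convolution residual network (stem + two basic blocks)
  with a configurable pooled width, for CPU-scale experiments and CI.

Training: cross-entropy, SGD momentum 0.9, batch size 16, learning rate
1e-3 for epochs 1–50 and 1e-4 for 51–100 (the defaults; desk-scale runs
compress the same two rates to roughly the first ⅔ and the final ⅓ of
their epoch budget). Per-epoch train/validation losses are recorded and
the weights with the lowest validation loss are retained. Inputs are
scaled to [0,1] and standardized with fixed constants (mean 0.5, sd 0.25).
Feature extraction runs in evaluation mode (batch-norm running statistics),
so features are independent of batch composition. All weights are
initialized from the run seed; training is deterministic given the seed.
Weights are always trained from scratch; pretrained initialization is not
supported.

## Fusion and classification

Fusion is concatenation in fixed order, [shallow, deep]; lengths add
exactly and provenance (source image id) must match. Classification is a
one-vs-rest decomposition into K binary RBF-kernel SVMs (scikit-learn's
libsvm solver; the package's contribution is the pipeline contract, not
the quadratic program), penalty C = 10, γ = the variance-scaled heuristic
1/(d·Var) unless overridden. Features are standardized per dimension with
statistics estimated on the training set only — necessary when
histogram-scale (≤1) and activation-scale coordinates are concatenated.
Ties between one-vs-rest decision values resolve to the lowest class index
in sorted label order. Fitted models persist with a version-stamped
metadata JSON (feature tag, dimension, configuration) so a stale model
cannot be applied to mismatched features.

## Evaluation

The confusion matrix counts true class (rows) × predicted class (columns).
Per class, one-vs-rest counts give accuracy = (TP+TN)/total, precision =
TP/(TP+FP), recall = TP/(TP+FN), F1 = 2PR/(P+R); any zero denominator
yields 0 with a logged warning. The aggregate row reports overall accuracy
(trace/total) and unweighted macro means of precision/recall/F1 — on the
balanced test sets produced by the generator, macro and support-weighted
averages coincide. The plain-text per-species report prints recall in its
Accuracy column, matching the convention of per-species results tables in
which a species' accuracy is its recall.

## Synthetic beak generator

Each image is a dark hooked silhouette on a white board (≈255): an
area-preserving elongated ellipse minus a circular "bite", which produces a
rostrum/hood hook, with fine sinusoidal pigmentation stripes inside the
silhouette. Two independent difficulty knobs in [0,1]:

* `shape_separation` scales class-specific offsets of the hood/crest
  elongation (±30% at full separation, area-preserving so silhouette area
  carries no class signal) and of the bite position (hook placement).
* `texture_separation` scales class-specific stripe periods (base 5 px,
  −40% to +45% at full separation). Stripe orientation (45° ± 10°) and
  phase are randomized per image, and stripe amplitude is proportional to
  the period, which equalizes gradient energy across classes — so the
  texture signal is carried by local intensity statistics (LBP's domain)
  and deliberately not by edge orientation or magnitude (HOG's domain).

Intra-class variation comes from per-image jitter of every silhouette
parameter (3–5%), a random similarity transform (rotation sd 3°, scale sd
4%, translation sd 4% of the half-side) and clipped Gaussian pixel noise
(sd 8 by default). The lower view is a mirrored variant with a shifted
hood/crest ratio. At zero separation the class-conditional distributions
are identical, so no classifier can exceed 25% expected accuracy.

What the generator does **not** emulate: photographic lighting and shadow,
JPEG artifacts (images are lossless PNG), ontogenetic and sexual
pigmentation variation, specimen damage, and the fine anatomical detail of
real beaks. Passing pipeline tests therefore demonstrate that the
implementation recovers the signals the generator plants — morphology for
HOG/deep, texture for LBP — not that the measured accuracies transfer to
beak photographs.

## Desk-scale experiment design

`beakfusion.experiments.TrialConfig` fixes the problem sizes used by the
end-to-end property checks so a full trial runs in seconds to ~30 s on one
CPU core: 128×128 renders, one view, HOG with C = 32 (324 dims), LBP with
R = 1, P = 8 (59 dims), `desk_small` at 32×32 input with a 128-wide pooled
feature, 25–30 epochs, and 2 augmented copies per training image for
backbone training (mirroring the protocol of training the CNN on an
augmentation-expanded set). Design choices worth recording:

* The deep input side is 32 px: downsampling destroys the stripe texture
  (periods fall below the pixel scale), so deep features read morphology
  only. This makes the three feature types genuinely complementary —
  the premise of fusion — and is why the fused variants beat each single
  feature type at intermediate difficulty.
* The "medium difficulty" condition used for the fusion-dominance check is
  shape = 0.4, texture = 0.75 rather than a symmetric setting: the LBP
  accuracy responds more weakly to its knob than HOG does to its, and
  these values place both shallow descriptors at comparable (65–70%)
  single-feature accuracy so that neither signal is negligible. With the
  texture channel uninformative, fusing two descriptors that both measure
  shape merely re-weights the same information and cannot exceed the
  better one.
* The high-separation recovery condition is shape = texture = 0.85 with 50
  images per class; the zero-separation chance check uses 24 images per
  class over 10 seeds and a lighter 6-epoch backbone, since no signal
  exists to learn.

## Known limitations

* The NumPy backbone is CPU-bound: `reference50` forward passes take
  roughly a second per 224×224 image and training it at scale is not
  practical — it exists as the faithful reference architecture and for
  dimension contracts; experiments train `desk_small`.
* The one-vs-rest SVM offers no probability calibration, and one-vs-one
  decomposition is not implemented.
* LBP here is the plain uniform variant; rotation-invariant codes would be
  needed for datasets without a consistent specimen orientation.
* The synthetic generator's realism limits are listed above; conclusions
  about real beak photographs require real data through the same pipeline.
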