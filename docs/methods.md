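# Methods

This note records the models and procedures tumorkit implements, the
parameters that matter, and the design choices made where the standard
formulations leave room.

## Phantoms: what the synthetic data emulates

The phantom generator stands in for a curated set of 2-D brain MR
slices with balanced tumor / non-tumor classes. Each phantom is an
elliptical "brain" (semi-axes 0.42 and 0.36 of the image side) at
intensity 0.35 on a dark background, with a smooth low-frequency
texture field (Gaussian noise smoothed at length 4 px, pointwise SD
0.03) and i.i.d. pixel noise (SD 0.02). Tumor phantoms add one
elliptical blob with radii drawn from 6–14 % of the image side, at
intensity 0.85 with a higher-variance internal texture (SD 0.10),
placed uniformly inside the brain with a margin so it fits entirely.
All intensities are on the unit scale; values are clipped to [0, 1].

Two properties are deliberate, because downstream stages rely on them:
tumors are *hyperintense* (the segmenter picks the brightest cluster)
and *texturally rougher* than brain tissue (so tumor ROIs carry more
co-occurrence contrast). Default size is 224 so phantoms feed the
classifier without resizing.

What the phantoms do **not** model: anatomy (ventricles, skull, gray /
white matter), bias fields, partial-volume effects, imaging artifacts,
multi-focal or hypointense lesions, and 3-D structure. Passing tests
therefore demonstrate that the pipeline's machinery is correct and
behaves as designed under its stated assumptions — not that it reaches
any particular accuracy on clinical data.

## Preprocessing

Raw 8-bit images are bilinearly resized to 224 × 224 (aspect ratio not
preserved — the standard CNN input convention), scaled to [0, 1] by
division by 255, and smoothed with a normalized Gaussian kernel
(σ = 1.0 resized pixels by default, truncated at 4σ, reflect
boundaries). The value range is tracked on the image object so double
normalization is a hard error rather than a silent scale corruption.
Blur runs after resizing, so σ is in units of resized pixels.

## Segmentation

Per-pixel features are scalar intensities by default; an optional mode
appends (row, col) scaled to [0, 1]. K-means++ seeding draws the first
centroid uniformly and each subsequent one with probability
proportional to the squared Euclidean distance to the nearest chosen
centroid. Lloyd iterations stop when the maximum centroid displacement
is ≤ 1e-4 intensity units or after 100 iterations. Defaults chosen
where the formulation is open:

- **k = 3** — dark background, brain tissue, hyperintense tumor.
- **Tumor cluster = highest centroid intensity** — consistent with the
  hyperintense-lesion assumption baked into the phantoms.
- **Empty clusters** are re-seeded at the point farthest from its
  nearest centroid, keeping k fixed and the run deterministic.
- **n_init = 10 restarts**, keeping the lowest-inertia run. Lloyd's
  algorithm from a single k-means++ initialization reaches the global
  optimum on only about half of small unstructured instances, and on
  intensity histograms it can split the dark background into two
  clusters and merge brain with tumor; ten restarts (the long-standing
  sklearn convention) make both failure modes rare.

Dice = 2|A∩B|/(|A|+|B|) is reported against ground truth; both masks
empty counts as 1.0.

## Texture features

The image is uniformly quantized into L = 32 levels over [0, 1]
(intensity 1.0 maps to level L−1). For each angle θ ∈ {0°, 45°, 90°,
135°} (offsets (0,+D), (−D,+D), (−D,0), (−D,−D) in (row, col) with row
0 at top) and distance D = 1, co-occurrences are counted over pairs
whose **both** endpoints lie in the ROI — boundary pixels never mix
tumor and background statistics. Matrices are symmetric by default and
normalized by the total pair count; features from several angles are
averaged arithmetically. An ROI too small to contain any pair at some
angle is an error naming the stage.

Two definitional choices where printed formulations of this feature
set are often garbled:

- **Energy** is the angular second moment Σp², and **entropy**
  −Σp ln p is reported as a separate auxiliary field, rather than
  mixing the two into one statistic.
- **Correlation** is the standard normalized GLCM correlation with
  marginal means and SDs, the only common statistic of that name that
  lands in [−1, 1]. A zero-variance (constant-ROI) matrix gets
  correlation 1 with a degeneracy flag — a constant region is
  perfectly linearly dependent by convention.

## Augmentation

One uniform draw per enabled transform — rotation ±20°, shear ±10°,
zoom 0.9–1.1, shifts ±10 % of each dimension, fair-coin horizontal and
vertical flips — composed into a single affine map about the image
center and applied in one bilinear resampling pass (sequential
resampling would compound interpolation blur). Vacated pixels are
filled by the nearest / reflect / constant rule; values stay in [0, 1].
Optional intensity jitter (gain 0.9–1.1, offset ±0.05) is off by
default. Augmented copies inherit labels but carry no ground-truth
mask: augmentation happens after segmentation and feature extraction
in the training pipeline, so transformed masks are never consumed.
The numeric ranges are conventional moderate settings and are all
config-exposed.

## Classifier

`small_cnn`: input (1, 224, 224) → three 3×3 stride-2 convolutions
with channels (8, 16, 32) and ReLU → global average pooling → dense
512 ReLU → dense 1 sigmoid. Inputs in [0, 1] are centered at zero
(x − 0.5) as part of the network definition; without centering the
all-positive inputs give poorly conditioned first-layer gradients and
the fixed 30-epoch budget is not enough to leave the initial plateau
on small datasets. Weights are He-initialized from the model seed;
all computation is float32 NumPy with hand-written backpropagation
(verified against central finite differences in the test suite).

Training: stratified 70:30 train/validation split, minibatches of 32,
30 epochs, binary cross-entropy with predictions clipped to
[1e-7, 1−1e-7], and bias-corrected Adam (lr 0.001, β₁ = 0.9,
β₂ = 0.999, ε = 1e-8). A `literal_eq15` flag switches off the bias
correction for side-by-side comparison with the uncorrected update.
The decision threshold is 0.5, with probability exactly 0.5 classified
as tumor. `input_mode="hybrid"` concatenates the six texture statistics
onto the pooled vector before the dense head, letting the classifier
combine learned spatial features with the engineered texture summary.

A `transfer_resnet50` backbone name is reserved for a frozen
pretrained 50-layer residual backbone under the same head; requesting
it without pretrained weights raises an explicit error recommending
`small_cnn`. The compact CNN is the default because it trains to
convergence in minutes on one CPU at the package's study sizes.

## Grad-CAM

The target is the pre-sigmoid score. Under global average pooling its
gradient on the last conv maps is spatially constant, so the channel
weights α_c reduce to ∂score/∂pooled_c divided by the map area. The
heatmap is ReLU(Σ α_c A_c), bilinearly upsampled to the input size and
min-max normalized to [0, 1]; an all-zero raw map stays all-zero
rather than dividing by zero. Localization is assessed by whether the
heatmap argmax falls inside the true mask dilated by 8 px — one cell
of the last conv grid (stride 2³), the heatmap's native resolution.

## Evaluation

Label 1 = tumor = positive. Any 0/0 metric cell evaluates to 0 with a
degeneracy flag so reports on degenerate splits still render. The
per-class report treats each class as positive in turn and adds
accuracy, macro (unweighted) and support-weighted averages, rendered
as aligned text and as JSON.

## Problem sizes and determinism

The pipeline's verification runs use: 20 phantoms for segmentation
recovery, 401 per class for the augmentation bookkeeping check,
200 per class × 3 seeds for classifier training, 30 per class
(noise-free) for the separable-set check, and 20 fresh tumor phantoms
for Grad-CAM localization — sizes at which every check completes in
minutes on a single CPU core. All randomness flows through
`numpy.random.default_rng` from explicit seeds; dataset item seeds are
spawned via `SeedSequence`, so every artifact is bit-reproducible from
(config, seed).

## Known limitations

- The phantom regime is far easier than clinical MR data; reported
  accuracies characterize the implementation, not clinical utility.
- Intensity-only clustering cannot separate a lesion that is not the
  brightest tissue class; the tumor-cluster rule is a stated
  assumption, not an inference.
- The co-occurrence features use one global quantization of [0, 1];
  per-ROI contrast stretching is not performed.
- Augmented copies lose their masks by design, so augmentation cannot
  currently feed mask-supervised training.
- The classifier is desk-scale; no pretrained backbone ships with the
  package.
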