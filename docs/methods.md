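# Methods

## The classification model

The core object is a 5-class patch classifier: a convolutional feature
extractor followed by global average pooling (GAP) and one fully connected
layer. Patches are square crops of a mammogram at a fixed pixel size
(256, 512 or 768 px at the reference resolution of 100 μm/pixel) labelled
background, benign calcification, malignant calcification, benign mass or
malignant mass. The production extractor is DenseNet-121 (growth 32,
blocks 6/12/24/16, single-channel stem), chosen for its parameter
efficiency: its extractor has ≈7M parameters against 21.3M for ResNet-34.
All spatial arithmetic is floor-rounded: a layer with kernel k, stride s,
padding p maps a side of n pixels to ⌊(n + 2p − k)/s⌋ + 1, giving the
extractor a spatial reduction factor of 32 and e.g. a 16×16×1024 feature
map for a 512×512 patch. For a 2850×2394 mammogram the same arithmetic
gives 89×74×1024; note that no single rounding convention yields 89×75
(ceil everywhere gives 90×75), so this package uses floor everywhere and
documents the width accordingly.

A trained patch classifier becomes a whole-image binary classifier by
removing GAP/FC, applying the extractor to the full image, and appending
an aggregation block — a bottleneck residual block (1×1 stride-2 C→C/4,
3×3 C/4→C/4, 1×1 C/4→C, with a strided 1×1 projection shortcut; batch
norm + ReLU post-activations) that halves the spatial dimensions and
preserves the channel count — followed by GAP and a single-logit sigmoid
"cancer score". The number of aggregation blocks is configurable
(default 1). On an input of exactly patch size the extended model's pooled
extractor features equal the patch classifier's penultimate features
bit for bit, because the weights are shared, and the tests assert exact
equality.

Three fusion architectures combine scale-specific branches:

* **multi-patch-size** — three whole-image classifiers built from patch
  sizes 256/512/768 applied to the same image;
* **multi-resolution** — one patch size applied to the image downsampled
  by factors 1/1.5/2 (100/150/200 μm effective resolution), with
  anti-aliased area-style resampling;
* in both, the three pooled feature vectors are concatenated (length 3C)
  and passed through an MLP — one hidden layer of 512 ReLU units and a
  sigmoid output, the smallest architecture deserving the name; and
* **FPN** — a single backbone tapped at strides 8/16/32, lateral 1×1
  projections to a common width, nearest-neighbour top-down pathway with
  3×3 smoothing, per-level pooling (plus per-level aggregation blocks in
  the whole-image form) and a concatenated classifier head; patch size
  768 by default so the deepest level still sees whole large lesions.

Because no GPU framework is a dependency, the package implements
reverse-mode autodiff over numpy (`mammoscale.nn`): conv2d via im2col with
a col2im backward, max/avg pooling, batch norm (batch statistics in
training, running statistics in inference), linear, concat, nearest
upsampling, softmax cross-entropy and binary cross-entropy. Gradients are
verified against central differences on smooth compositions; kinked ops
(ReLU, max-pool) are verified by construction tests. Everything runs in
float32. The `tinycnn` backbone (3 conv/BN/ReLU/maxpool stages, 16/32/64
channels, reduction 8, 23 408 parameters) exists so that every contract is
testable on a CPU in seconds; it is a first-class backbone, not a mock.

## Patch extraction

From each annotated image: one *fixed* patch centred on each lesion
(clamped inward at image borders — never zero-padded, to keep patches
in-distribution); when a lesion's bounding box exceeds the patch in either
dimension it is instead tiled by a ⌈h/p⌉×⌈w/p⌉ grid anchored at the bbox
top-left, with the last row/column shifted inward to stay on the image;
then *random* patches centred on uniformly drawn lesion-mask pixels,
accepted greedily only if their IoU with every previously accepted lesion
patch of the image stays below 0.5, topping the per-lesion count up
towards a floor of ten lesion patches per single-lesion image; and exactly
ten *background* patches whose boxes intersect no lesion mask and lie at
least half inside the Otsu-thresholded breast foreground. All mandatory
fixed/grid boxes of all lesions are collected before any random sampling,
so every random patch is constrained against every other lesion patch.

Two constraints interact and cannot always both hold:

* the ten-patch floor is unreachable for lesions much smaller than the
  patch — two p-pixel boxes both containing a tiny lesion have IoU
  (p−s)/(p+s) for centre offset s, so IoU < 0.5 forces offsets > p/3 and
  caps the number of admissible boxes. The sampler honours the IoU bound
  and delivers as many random patches as it allows (bounded at 100
  consecutive rejections).
* fixed/grid patches are mandatory, so two adjacent lesions (or an edge-
  shifted grid row) can produce mandatory boxes with IoU ≥ 0.5. The bound
  is therefore guaranteed for every pair involving a random patch, and for
  all pairs on single-lesion images away from borders.

A patch overlapping several lesions takes the class of the lesion with the
largest mask-overlap area (ties to annotation order); a grid tile covering
only a lesion-free corner of the bbox is labelled background.

## Training recipe

SGD with momentum 0.9 (no weight decay) under a cosine-annealed learning
rate lr(t) = lr₀·½(1 + cos(πt/T)) stepped per batch. Class imbalance is
handled by sampling with weights ∝ 1/class-frequency, making expected
per-class draw rates uniform (verified by a χ² test at 10⁴ draws).
Augmentation is flips and 90° rotations only — label-preserving and free
of interpolation artifacts. Each configuration is trained `n_runs` times
with seeds `seed_base + i` (reference protocol: 10 patch runs, 5
whole-image runs) to obtain mean ± sd and cross-run significance. Training
is bit-reproducible given the seed. Fine-tuning scopes freeze parameters
outside a named set of prefixes; the `last_two_blocks` preset keeps the
last two backbone blocks plus all head parameters trainable, and the tests
assert frozen weights are bit-identical after training.

Whole-image training freezes the patch-trained extractor by default and
trains only the aggregation block and head; extractor feature maps are
then computed once and cached across runs and epochs, which is what makes
repeated CPU runs cheap. Fusion training likewise freezes the branches and
trains only the MLP, on cached concatenated feature vectors; every
training image contributes its 8 flip/rotation orientations (branch
features are not orientation-invariant, so this multiplies the MLP's
effective training set) and, for the very small phantom training sets,
full-batch gradient steps are used. End-to-end fine-tuning of the
extractor inside the whole-image stage is deliberately not provided.
Learning rates, batch sizes and epoch counts have no published reference
values; the defaults are working values for the phantom tasks and are
recorded in each experiment's config hash.

## Evaluation protocol

Lesions are grouped by maximal dimension — the larger side of the mask's
tight bounding box — into small (< 25.6 mm), medium (25.6–51.2 mm) and
large (≥ 51.2 mm); boundary values join the larger group (the source
convention is unstated; this choice is centralised in one function).
Patch classifiers are scored per lesion type × size group with:

* normal-vs-abnormal AUC: abnormality score 1 − P(background) over the
  group's patches against an equal number of background patches,
  subsampled once per (group, seed) so all models share the subset;
* benign-vs-malignant AUC: malignancy score P(malignant calc) +
  P(malignant mass) within the group, malignant positive.

Either metric is reported missing when a group lacks enough examples (or,
for the pathology AUC, contains a single pathology). AUC is the area under
the empirical ROC (Mann–Whitney with tie half-credit), computed with
scikit-learn and tested against an exhaustive pair-counting oracle.

Whole-image classifiers report AUC plus specificity and accuracy at the
operating point whose sensitivity is at least 0.75: the threshold is the
largest score value whose sensitivity meets the floor, without ROC
interpolation, so the reported Se is the smallest attainable value ≥ 0.75
(exactly 0.75 when 100 positives have distinct scores). Models are
compared with the one-sided Welch t-test (Welch–Satterthwaite degrees of
freedom) on per-run metrics against a named baseline, binned as
ns / * (p<0.1) / ** (p<0.05) / *** (p<0.01) / **** (p<0.001) with strict
inequalities. When both variances are zero and the means are equal the
p-value is 0.5 by convention.

## Grad-CAM

Heatmaps explain the ground-truth class (not the predicted one) from the
last convolutional feature map: channel weights are spatial means of
∂logit/∂feature-map, the map is ReLU(weighted sum), max-normalised and
bilinearly upsampled to the patch. An all-zero gradient yields a flagged
all-zero heatmap. Localization is scored as the CAM argmax falling within
one feature cell of the lesion mask, since the map's native resolution is
one cell (8 px for tinycnn).

## The phantom generator

Phantoms emulate the properties the pipeline actually consumes: a
breast-shaped half-ellipse foreground on a dark background; band-limited
parenchyma-like texture (white noise smoothed by a Gaussian of
configurable σ, default 8 px, scaled to std 0.06 of the dynamic range over
a base level of 0.38); masses as soft-edged ellipses with a sinusoidal
radial border perturbation whose amplitude encodes border irregularity
(rasterised, measured, and rescaled once so the realized maximal dimension
stays within ±10% — in practice ±5% — of the requested physical size);
calcification clusters as n hard dots within the cluster extent, with two
anchor dots pinning the bounding box to the requested size. Malignancy is
a learnable proxy: malignant masses get border irregularity 0.7 vs 0.2 and
contrast 0.45 vs 0.30 (margin 0.15); malignant clusters get more, finer
dots (18 × r2 vs 8 × r3). Lesions are placed uniformly inside the eroded
breast mask, mutually disjoint with a 2 px margin, with bounded retries
and an explicit error naming the offending lesion. Images are written as
16-bit PNG with JSON sidecars (schema-versioned, RLE masks, bboxes derived
from masks) and a CSV manifest with a stratified train/val split.

No published intensity statistics exist for the source data, so the
intensity model is a free parameter of the phantom. What passing phantom
tests show is that the *pipeline machinery* behaves as specified —
extraction geometry, training dynamics, scale trade-offs, evaluation
plumbing — not that any particular clinical performance level would be
reached on real mammograms: phantoms lack tissue superposition, vessels,
skin folds, scanner noise spectra and the hard benign/malignant boundary
cases of real pathology.

## The multi-scale recovery experiment

The behavioural acceptance test reproduces the qualitative core finding —
no single patch size suits all lesion sizes — at desk scale. Conditions
(chosen once, after a pilot run, then frozen): 320×256 phantoms at
800 μm/pixel, so small-group lesions (8–24 mm) are 10–30 px and
large-group lesions (53–75 mm) are 66–94 px; a training set of 30 images
and an evaluation set of 40, drawn with mass and calcification lesions of
both size groups plus 34% normals; tinycnn patch classifiers at patch
sizes 32 and 96 (the same small/large ratio to lesion size as 256/768 at
100 μm); 4 patch epochs, 12 whole-image epochs, 60 full-batch fusion
epochs; 5 seeds. Checked, as medians over seeds: the 32-px classifier
beats the 96-px one on small-mass detection AUC and vice versa on large
masses (patch-level, balanced subsets), and the multi-patch-size fusion's
image-level AUC is within 0.02 of its best branch. In the pilot the fusion
exceeded the best branch (median 0.87 vs 0.81).

## Numerical and degenerate-input choices

* Floor rounding everywhere in shape arithmetic; inputs smaller than the
  reduction factor are rejected.
* Downsampling by factor 1 is a bit-exact identity; integer factors of
  constant images are constant.
* RLE masks are row-major alternating run lengths starting with zeros;
  round trips are property-tested.
* Batch-norm eps 1e-5, momentum 0.1; Kaiming-normal conv init and uniform
  linear init from a seeded generator, so model construction is
  deterministic given a seed.
* Training aborts with a diagnostic on a non-finite loss.
* An image-level label is "cancer" iff any lesion is malignant.
* The maximal dimension of a lesion is the larger tight-bbox side (not a
  Feret diameter); stated here because the source convention is unknown.
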