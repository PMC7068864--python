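# Methods

`lesionclass` implements a two-route pipeline for binary dermoscopy lesion
classification (benign nevus vs malignant melanoma, malignant always the
positive class), plus the synthetic data that exercises it and the
evaluation machinery that scores it.

## Synthetic lesion generator

The generator emulates the two visual regimes that separate the classes in
dermoscopy:

* benign — near-elliptical border, one homogeneous lesion color;
* malignant — irregular border and several heterogeneous color patches.

A lesion is the star-convex region `dist(p, centre) <= r(theta)` with

    r(theta) = r_ellipse(theta) * (1 + irregularity * s(theta)),

where `r_ellipse` is the radial function of a rotated ellipse (axis ratio
drawn in [0.7, 0.95]) and `s` is a band-limited harmonic noise (harmonics
2–6, random amplitudes/phases) normalised to peak amplitude 1.
Star-convexity guarantees each mask is a single connected, hole-free
component, which downstream shape features assume. At `irregularity = 0`
the radial comparison is algebraically identical to the ellipse inequality,
so the zero-perturbation mask is an exact rasterised ellipse.

Color heterogeneity is a seeded Voronoi partition of the lesion interior:
`n_color_patches` sites are drawn among lesion pixels and each pixel takes
the palette color of its nearest site. Defaults: benign irregularity 0.03
with one light-brown patch; malignant irregularity 0.35 with four patches
(dark brown, near-black, red-brown, blue-gray) on a light skin-tone
background, additive Gaussian pixel noise sd 0.02, 64x64 frames. The
malignant preset uses a slightly smaller mean radius (0.20 vs 0.28 of the
frame) so that its radial excursions still fit with margin.

POIs: the first POI is the mask centroid (snapped into the mask); for
multi-patch lesions one additional POI is placed at each color patch's
centroid (snapped onto that patch). This mirrors the acquisition contract
that every relevant spot is marked: the region-growing criterion compares
candidate pixels against the *originating seed's* gray value, so a dark
patch with no seed of its own would otherwise be unreachable by design,
not by defect.

What the generator does **not** emulate: hair and ruler artifacts, vignetting,
specular highlights, smooth color gradients, multiple lesions, darker skin
tones. Passing benchmarks therefore demonstrate the pipeline's mechanics
and internal consistency — not clinical performance on real dermoscopy
archives; the synthetic classes are far more separable than real data
(the benchmark accuracies near 1.0 reflect that; reported real-archive
accuracies for pipelines of this kind sit around 0.6–0.75, which shows how
much harder the real task is).

## Segmentation

Fixed preprocessing order: RGB → gray (Rec. 601 luma, weights sum to 1) →
3x3 median with zero padding (the middle of the nine sorted neighbourhood
values; border pixels see padded zeros) → linear contrast stretch onto
[0, 1] (constant images pass unchanged) → seed-relative region growing →
morphological refinement.

Region growing: a pixel joins the mask iff it is reachable from some seed
through pixels whose gray distance to that seed's value is at most the
similarity threshold. Comparing against the originating seed (not a running
region mean) makes the result a connected component of a thresholded
indicator image — deterministic and independent of both pixel visit order
and seed order. Defaults: threshold 0.15, 8-connectivity.

Refinement: binary closing with a disk of radius 2 (fills holes below the
closing scale, smooths the border by at most that radius), then removal of
components smaller than 64 px. If refinement deletes every seeded
component, an empty-ROI error is raised rather than returning background.
On the default synthetic presets the recovered masks overlap ground truth
with Jaccard ≥ 0.98 (the tested invariant is ≥ 0.8).

## The 12 descriptors

Order and semantics are fixed (CSV header `f1_mean_r` … `f12_unfilled_ellipse`):
mean RGB (f1–f3) and mean HSV (f4–f6, hue averaged circularly as a vector
mean of angles) over the ROI; a color-structure scalar (f7); two
color-layout scalars (f8–f9); and three shape descriptors (f10–f12).

The MPEG-7 color structure and color layout descriptors are vectors; this
package reduces them to the fixed scalar budget:

* **f7** — slide an 8x8 window (stride 1) over the ROI bounding box; for
  each of 32 product-quantized HSV colors (8 hue x 2 saturation x 2 value
  bins) count the windows containing at least one ROI pixel of that color;
  f7 is the Shannon entropy of the normalised histogram divided by log 32.
  One color → 0; maximally even color structure → 1.
* **f8, f9** — partition the bounding box into an 8x8 grid of mean ROI
  colors (cells without ROI pixels take the overall ROI mean, so background
  never leaks in), take the orthonormal 2-D DCT-II of the grid's luminance,
  and report the first two non-DC zigzag coefficients (0,1) and (1,0)
  through the affine squash `clip(0.5 + c/2, 0, 1)`. The scale 2 was chosen
  once from the coefficient range the generator produces (|c| ≲ 0.6) so the
  squash stays in its linear region; a constant ROI maps to the 0.5 zero
  point.

Shape features use the mask's moment ellipse: centroid and orientation from
the second central moments, semi-axes proportional to the covariance
eigenvalue square roots, rescaled so the ellipse area equals the mask pixel
count. f10 = sqrt(minor/major eigenvalue) ∈ (0, 1]; f11 = fraction of the
ellipse covered by the mask; f12 = fraction of the mask escaping the
ellipse. Compact lesions score f11 → 1, f12 → 0; ragged borders leak
outside. Degenerate (collinear) masks and masks under 5 px raise errors.

Features are min-max normalised to [0, 1] with parameters learned on the
training matrix; test values are clamped and constant training columns map
to 0.5.

## Classifiers

k-NN (default k = 5, Euclidean distance on normalised features): majority
vote; the malignancy score is the malignant fraction among the k
neighbours so ROC analysis applies; an even-vote tie goes to the single
nearest neighbour's label, and equal-distance rank ties resolve to the
lower training-row index. The SVM is an RBF-kernel SVC (C = 1,
gamma = 1/(12 · Var(X)), i.e. scikit-learn's `scale`); its score is the
signed decision value oriented toward malignant. The SVM optimiser is
deliberately delegated to scikit-learn — only its I/O contract is owned
here — whereas the k-NN vote is written out because its tie rules are part
of the contract.

## The 16-layer network

`build_lesion_net` emits a declarative layer list following the VGG16
recipe: conv blocks of (2, 2, 3, 3, 3) layers with (64, 128, 256, 512, 512)
filters, every convolution 3x3 / stride 1 / zero-padded (spatial size
preserved), ReLU after each, a 2x2 / stride-2 max pool closing each block;
then FC 4096 + ReLU + dropout, FC 4096 + ReLU + dropout, FC K, softmax —
13 conv + 3 FC trainable layers, 5 pools, default input 256x256x3, K = 2.
Dropout keeps probability is 0.5 on FC6/FC7 (inverted dropout, active only
during training).

Reference operators define exact semantics: `conv2d` is the zero-padded
'same' cross-correlation (or convolution proper with the kernel rotated
180°), `maxpool` uses non-overlapping windows with floor semantics on odd
trailing dims (25% of elements survive a 2x2/stride-2 pool on even dims),
`softmax` rows form a probability simplex, and the multinomial logistic
loss is the mean negative log-probability of the true class. The batched
training layers are tested against these operators and against central
finite differences.

Initialisation ("filler") profiles:

* `gaussian` (default) — conv: fan-in-scaled uniform weights, constant
  bias 0.2; FC6/FC7: Gaussian sd 0.005, bias 1; FC8: Gaussian sd 0.01,
  bias 0 (the classic Caffe-era VGG fine-tuning fillers).
* `reference` — fan-in-scaled uniform with zero bias on every trainable
  layer.

The fan-in-scaled uniform limit is `sqrt(6/fan_in)` (the He limit for ReLU
gain): with a plain `1/fan_in` scale, activations attenuate roughly
six-fold per layer and no signal survives 13 convolutions. The desk-scale
benchmark uses the `reference` profile throughout because the
near-zero-variance Gaussian FC fillers cannot break symmetry at reduced
width and a 300-image budget — training stalls at the uniform-predictor
loss ln 2. The architecture (counts, widths, kernels) is identical in both
profiles.

Training is momentum SGD (default learning rate 0.001, momentum 0.9, batch
25, 30 epochs) on the multinomial logistic loss, with hand-derived
backward passes (verified by numerical gradient checking) and every source
of randomness — shuffling, dropout masks, fillers — drawn from the config
seed. Rates of 0.01–0.003 were found to drive the float32 desk-scale net
into a dead-ReLU constant-output collapse; 0.001 descends reliably.

The case representation (`embed`) is the post-ReLU FC7 activation — the
last hidden layer, 4096-d at full width — rather than the 2-d logits:
retrieval needs a rich representation, and the 2-d softmax input collapses
all within-class structure. Inference never applies dropout, so embeddings
are deterministic.

## Evaluation

From confusion counts (TP/TN/FP/FN, malignant positive): precision,
recall/sensitivity, specificity, F-measure (harmonic mean of precision and
recall) and accuracy. Zero denominators raise a flagged error instead of
silently returning 0. Internally everything is unrounded; the display path
(`rounded_report`) rounds precision/recall first and computes the displayed
F-measure as the harmonic mean of the *rounded* values — the convention
under which published 2-decimal benign/malignant score tables in this line
of work are internally consistent (with unrounded inputs one such row's
printed F-measure is off by 0.01).

ROC and PR curves come from an explicit threshold sweep over the unique
score values plus ±infinity endpoints, with trapezoid AUCs; the ROC AUC
equals the Mann–Whitney pair statistic with ties at half weight (tested).

## Case base

Cases couple a network embedding, the 12-feature vector, the label and a
free recommendation text. Retrieval is exact k-NN under Euclidean distance
over embeddings (or feature vectors, by option), with deterministic ties
by case id; a query's class is the majority label of the retrieved cases.
Persistence is a JSON manifest plus a binary embedding matrix; round-trips
preserve rankings bit-exactly.

## Reference benchmark (problem sizes)

The shared benchmark configuration (`lesionclass.benchmark`) generates 150
training and 50 test images per class at 64x64 — mirroring the 300/100
first-round split of the study conditions — and runs both routes: the
handcrafted-feature route with k-NN and SVM, and the deep route at width
multiplier 0.25 (channels 16/32/64/128/128, FC width 1024) trained 12
epochs. The reduced width and input size keep a full run to a few minutes
on a single CPU while preserving the architecture's structure. Regression
floors asserted by the suite: k-NN and SVM test accuracy ≥ 0.9, CNN test
accuracy ≥ 0.8, retrieval accuracy ≥ 0.8, mean segmentation Jaccard ≥ 0.8.

## Known limitations

* The synthetic classes are linearly separable in several single features;
  benchmark scores near 1.0 say nothing about real-archive difficulty.
* The NumPy training engine is single-threaded desk-scale tooling: no GPU,
  no batch normalisation, no augmentation applied by default during
  training (the augmentation ops are provided as library functions).
* Region growing assumes the lesion is darker or lighter than skin at a
  roughly uniform offset per patch; lesions whose gray value matches the
  background within the threshold would leak.
* The full-width 256x256 network is buildable and trainable but not
  exercised end-to-end by the suite (memory/time scale); tests cover it
  structurally and cover the engine at reduced width.
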