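# Methods

## Problem setting

The package implements a histopathology analysis stack for duodenal
biopsy images from three diagnostic groups: healthy controls, celiac
disease (CD) and environmental enteropathy (EE). The two diseases are
histologically overlapping small-bowel enteropathies; the pipeline's
goal is (a) to classify biopsies from unannotated images, (b) to trace
which tissue structures drive the classifier's internal features, and
(c) to relate those features to noninvasive biomarkers so that, in the
long run, tissue phenotypes can be estimated without endoscopy.

Because real slide cohorts cannot be redistributed, the package ships a
first-class synthetic-data generator that reproduces the *statistical
shape* of such a cohort — multi-image cases in three classes, site-level
staining shifts, and biomarkers linked to latent texture parameters —
so every stage is testable end to end.

## Image model (synthgen)

Each case carries a latent texture vector
(blob density per megapixel, blob eccentricity, ridge amplitude) drawn
around its class means with multiplicative jitter (default 10%).
Images are rendered as:

- a pale eosin-pink background (231, 187, 201);
- sinusoidal intensity bands ("ridges", a minimal analogue of villus
  texture) with the case's amplitude, random orientation and phase, and
  a class-configurable period;
- dark hematoxylin-purple ellipses ("blobs", standing in for secretory
  cells) with Poisson counts at the case's density; eccentricity
  reshapes ellipses at constant area, and a per-class equivalent-area
  radius sets their size;
- i.i.d. Gaussian pixel noise, then a constant per-site RGB offset in
  [-30, 30] (the simplest model of inter-laboratory H-E staining
  differences), clipped to [0, 255].

The generator is a pure function of (spec, seed): identical inputs give
byte-identical PNGs. Latent vectors are persisted in a manifest sidecar
so biomarker links remain reproducible after a round trip.

What the generator does *not* emulate: real histological morphology
(crypts, villi as structures, cell boundaries), stain physics,
scanner artifacts, or spatial correlation between images of one case
beyond their shared latent vector. Passing tests on synthetic cohorts
therefore demonstrate that the pipeline's machinery is correct and that
its protocols are leakage-free — not that the classifier would reach
any particular accuracy on real slides.

## Preprocessing (imgprep)

Slides are tiled into non-overlapping 1360 x 1024 images (partial
border strips discarded — the network input is fixed-size). Training
augmentation takes ten uniformly random 1000 x 1000 patches per image
plus their horizontal and vertical reflections (30x). Test-time
extraction is deterministic: one central and four corner patches, each
with both reflections (15 per image). Color augmentation is gamma
correction, out = round(255 * (in/255)^gamma), with gamma drawn
uniformly per patch from [0.5, 2.0]; CLAHE on the luminance channel is
available but off by default, and no color augmentation is applied at
test time. Offsets are 0-based (row, col) from the top-left; the center
offset uses floor division.

## Network (cnn)

Four convolution blocks — zero-padded same-size convolution (stride 1)
+ ReLU + max pooling — with 16/32/32/32 feature maps, 5x5/5x5/5x5/3x3
kernels and 2/4/5/5 pooling windows, then one 1024-neuron fully
connected layer, dropout p = 0.5, and a 3-way softmax over the fixed
class order (control, CD, EE). Pooling stride equals the pooling
window; with a 1000 x 1000 x 3 input the grid shrinks 500 → 125 → 25 →
5, so the fourth convolution emits 25 x 25 values per map and the
flattened fan-in is 5·5·32 = 800. The input side must be divisible by
the pooling product (200), and the fully connected fan-in adapts to it.

The implementation is self-contained NumPy: convolutions are computed
as sums of shifted batched matrix products (efficient at small channel
counts on one CPU), max-pool gradients route to the first maximum of
each window, dropout is inverted and seeded, and training minimizes
categorical cross-entropy with mini-batch Adam (default lr 1e-3, batch
32, 20 epochs — the epoch count deliberately small to limit
overfitting). Weights use seeded He initialization. Analytic gradients
are verified against central differences to 1e-4 relative error on a
small float64 configuration in the test suite. Inference disables
dropout and is deterministic.

Aggregation: a patch yields a probability triple; an image is the mean
of its 15 test-patch triples (patches that coincide pixel-for-pixel are
computed once and weighted by multiplicity — exact and faster near the
degenerate geometry); a case is the mean of its image triples, labeled
by argmax with ties broken by class order.

## Evaluation (evalkit)

Cross-validation is case-preserving: folds partition *cases*, never
images, so no patient contributes to both sides of a fold. Folds are
class-stratified (within each class fold sizes differ by at most one).
Reported metrics: per-image accuracy (each image classified
individually), per-case accuracy (after probability averaging), the
aggregated 3x3 confusion matrix, and the false-negative rate — defined
as diseased cases (CD or EE) predicted control over all diseased cases,
the clinically meaningful direction for a screening tool; a
denominator-over-all variant is available behind a flag.

The intercountry transfer protocol trains one model per leave-one-out
subset of the training site's target-class cases (control/CD cases are
randomly allocated per class, seeded and logged) and evaluates each
model on every held-out-site case, yielding a 2 x n table of per-image
and per-case accuracies, plus an optional model trained on a named case
subset.

## Traceback (traceviz)

For each of the 32 final-layer maps, the single highest activation on
the final convolution grid is located (ties: smallest row-major index)
and projected to source pixels through the receptive-field recurrence
(sizes grow by (k-1)·jump per convolution and (w-1)·jump per pool; the
jump multiplies by each pool stride). For the default architecture a
final-layer unit sees a 164-pixel field with 40-pixel stride between
neighbors. The exported *segment* is a fixed 142 x 142 crop centered on
the traced field's center (shifted inward at borders so the crop size
is preserved): 142 is the conventional artifact size for these
galleries, while the analytic field size remains available from
`receptive_field_geometry`. Top-k galleries (default k = 9) rank the
per-image peaks across an image set in non-increasing activation order.
"Deconvolution" here means this highest-activation traceback, not
transposed-convolution image synthesis.

## Activation statistics (actstats)

Each image contributes the 32 per-map maxima of the final convolution
grid. For a target class, a one-sided Welch (unequal-variance) t test
per filter asks whether the target's activations exceed those of the
pooled other classes; Holm step-down adjusted p values accompany the
raw ones. The observational unit is the image — patch-level sampling
would pseudo-replicate cases and is available only behind a loudly
logged flag. A pairwise (class vs class) mode exists for finer
contrasts.

## Biomarker correlation (biocorr)

Case-level targets are the per-map maxima over all the case's images,
with the realizing segment stored per (case, map). One lasso per map is
fit on markers standardized with training-fold statistics only; the
penalty is selected by inner 5-fold cross-validation. Predicted
activations are clamped at zero (rectified activations are nonnegative;
clamping provably never increases the MSE against nonnegative truth —
an alternative drop-from-scoring mode exists since the underlying
convention is ambiguous). Evaluation reports the mean per-case MSE
(mean over 32 squared differences) and the variance of fold MSEs, on
both raw and standardized activation scales. Reconstruction matches
each estimate to the training segment with the nearest stored
activation (ties: earliest insertion), sorted by absolute difference.
Marker importance uses a random forest (500 trees by default, seeded)
with permutation importance averaged over maps; backward elimination
removes the least important marker, refits, and re-cross-validates down
to one marker, reporting the MSE curve and its argmin subset.

## Desk-scale configuration (presets)

Full-size experiments (1000 x 1000 inputs, full widths) are impractical
for routine testing, so `presets` pins a desk-scale configuration used
by the test suite and the acceptance script:

- cohort: 30 cases (10 per class), 5 images each, 200 x 200 px;
- network: identical depth, kernels and pooling schedule, narrowed to
  4/8/8/16 maps with a 32-neuron fully connected layer, input 200;
- training: 20 epochs, batch 8, lr 3e-3, seeded;
- augmentation: one full-frame patch per image, no reflections or
  gamma, so the augmentation path is exercised at zero extra cost.

A structural consequence of the 200-pixel input is that the final grid
is 1 x 1: the classifier head sees one *global maximum* per feature
map, so class signal carried by blob counts is invisible to it. The
desk-scale textures therefore separate classes along axes a maximum can
see — blob radius (3.5/6/9 px), eccentricity (0.10/0.50/0.85) and ridge
amplitude (40/12/2 on a 30 px period, pixel noise sd 2) — which is the
"widely separated, separable by design" regime that the end-to-end
protocol checks require. Measured on one CPU, the full 10-fold
case-preserving cross-validation completes in about nine minutes and
reaches 1.00 per-case / 0.98 per-image accuracy with a zero
false-negative rate.

## Numerical and design notes

- Probability triples are validated to the simplex within 1e-6; image
  and case means stay on the simplex by convexity, no renormalization.
- Max-pool gradient ties route to the first maximum (deterministic);
  exact ties are measure-zero for continuous inputs but common at
  zeroed ReLU outputs, where the choice is inconsequential.
- All stochastic components (generator, initialization, shuffling,
  dropout, fold splitting, forest fitting) take explicit seeds; fold
  models derive their seed from the experiment seed and fold index.
- Degenerate inputs fail loudly: empty manifests, missing classes in a
  training fold, out-of-grid positions, empty segment libraries and
  missing markers raise named errors rather than propagating NaNs.
- Checkpoints are a single zip of weights plus a JSON header (config,
  class order, seeds, loss history), version-tagged.

## Known limitations

- The synthetic image model is deliberately minimal; accuracy numbers
  on it say nothing quantitative about real H-E slides.
- The published real-data headline numbers (93.4% per-case accuracy,
  2.4% false-negative rate, biomarker MSEs near 0.08) require the
  original cohorts, which are not deposited; they are out of scope here.
- Stain normalization and gradient-weighted class-activation mapping
  are not implemented (deliberate non-goals).
- The NumPy network trains small configurations briskly but is not
  intended for full-scale training runs that a GPU framework would
  serve better.
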