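# Methods

## Problem setting

Intraspecific variety identification assigns a whole-plant RGB image to one
of C accessions of a single crop species. Each image carries its acquisition
context in the filename, `accession_tag_date_viewpoint.ext`: the accession
label, a free-form tag (replicate/plant identifier), an orderable sampling
date (ISO date or days after sowing) and the camera viewpoint (front or
side). Manifests built from such folders are the unit every later stage
consumes. Splits are stratified per accession (`round(f·n)` test images per
class, capped at n−1) so that every class remains trainable; a global
unstratified split is available behind a flag. Date tokens order numerically
when every token parses as an integer and lexicographically otherwise, which
handles both calendar-date and days-after-sowing naming styles.

Filename grammar: the stem is split on underscores into first = accession,
last = viewpoint, second-to-last = date, and everything between absorbed
into the tag, so tags may themselves contain underscores.

Plant-focused cropping (optional, off by default) takes an Otsu threshold on
the HSV saturation channel, keeps the bounding box of the largest connected
component, pads it by 5 %, and falls back to the full frame when nothing
exceeds the threshold. Resizing is bilinear with antialiasing. These choices
suit plants photographed against uniform greenhouse backgrounds; cluttered
field imagery would need a real segmentation model.

## GMMA

Growth-stage and multi-view mixed augmentation interpolates pairs of
same-accession training images with fixed weight λ (default 0.5, not
randomized per pair):

* temporal: same viewpoint, date t with the next date t+1;
* viewpoint: front with side at the same date;
* view-stage: front at t with side at t+1.

Only pairs satisfying one of these three constructions are mixed — not all
pairs in the accession group — and "next date" means the immediate successor
among the dates actually present for that accession (per viewpoint for
temporal mixing), so irregular sampling schedules work. When a (date,
viewpoint) slot holds several images the Cartesian product of candidates is
enumerated. View-stage mixing is directional (front→side); the mirrored
variant is available via `view_stage_symmetric` but off by default, matching
the printed formulation. On a complete D-date, two-view grid an accession
yields D viewpoint + 2(D−1) temporal + (D−1) view-stage = 4D−3 jobs, a
closed form the tests check against a brute-force all-pairs oracle.

Mixing is pixel-wise convex combination in floating point, rounded and
clipped to 8-bit, so mixed PNGs re-enter the same pipeline as raw images.
Labels are never interpolated (both parents share the accession), the test
split is never augmented, and accessions are never mixed. Mixed files are
named `<accession>_mix-<type>_<dateL>-<dateR>_<viewL><viewR>.png` with a
numeric suffix on collision.

## Model and training

The offline-trainable backbone, `tiny`, is a small CNN implemented directly
in NumPy with explicit backpropagation: a per-image standardization layer
((x−mean)/sd over all pixels, exact gradient), a 2×2 average-pool stem, three
3×3 stride-1 'same' convolution blocks (16/32/64 channels, ReLU, 2×2 max
pooling after the first two), global average pooling and a linear head. The
total downsampling before the last convolution is 8×, so a 96×128 input
yields 12×16 feature maps there. Convolutions use im2col and float32 GEMM;
weights are He-initialized from a seeded generator, making runs
bit-reproducible per machine. The classical ImageNet backbones (VGG19,
ResNet18, MobileNetV2, InceptionV3, EfficientNet, DenseNet121) are kept in
the registry so that requesting one raises an actionable error: they require
an external deep-learning runtime and published pretrained weights that this
package deliberately does not bundle, and when such a runtime is available
the intended protocol is full fine-tuning of all parameters after replacing
the final fully connected layer with a C-way head.

Training is mini-batch SGD with classical momentum at a constant learning
rate (defaults lr 0.01, momentum 0.9, batch 64). Each image is horizontally
flipped with probability 0.5 at load time, re-drawn every epoch from the
run's seeded generator; mixed images participate like raw ones. The loss is
either cross-entropy or adaptive cross-entropy,

    L_ACE = (1/N) Σᵢ (1 + α(1−cᵢ)) · ceᵢ ,

with cᵢ the argmax-correctness indicator recomputed from the current forward
pass and treated as a constant in the gradient (ties break toward the lowest
class index). The global gradient norm is clipped at 5.0 before each update
— in ordinary steps the norm is far below this, so the stated recipe is
unchanged, but it prevents the reweighted loss from amplifying early steps
(when every sample is misclassified the gradient doubles, and with momentum
0.9 the effective step would be ~20× the learning rate) into a bad basin.
α defaults to 1.0, which makes the misclassified-sample term
comparable in magnitude to the base loss; α = 0 is bit-identical to plain
cross-entropy, and L_ACE ≥ L_CE always, with equality exactly when α = 0 or
every sample is correct. Probabilities are floored at 1e−12 before logs. A
step-decay schedule is not applied by default — only the stated lr/momentum
recipe.

## Evaluation

Accuracy is Σ TPᵢ/N; precision, recall and F1 are computed per class from
the confusion matrix and macro-averaged. Ratios with zero denominators are
defined as 0 and kept in the macro mean: with hundreds of classes and 20 %
test fractions, classes with no test images or no predictions occur, and
dropping them would inflate the averages. Per-stage accuracy tables group
test images by their stage token (sampling date or named stage), ordered
naturally, with missing tokens pooled under `unstaged`; the image-weighted
mean of per-stage accuracies equals overall accuracy whenever the stages
partition the test set. The confusion partition splits errors by whether the
predicted and true classes share a user-supplied group (e.g. subspecies);
phenological binning (pre-heading / heading–MPA / MPA–pre-harvest / harvest)
requires per-accession milestone dates that the package does not invent — a
milestones table can be joined onto the stage column by the caller.
Relative improvement between two accuracies is 100·(new−baseline)/baseline,
reported to two decimals.

## Grad-CAM

For target class v the gradient of the pre-softmax logit y_v is taken with
respect to the post-ReLU feature maps of a chosen convolutional layer
(default: the last one). Channel weights are the spatial means of those
gradients; the heatmap is the rectified weighted channel sum, bilinearly
upsampled to the input size. Raw values are kept in the returned structure;
min–max normalization to [0, 1] is applied only for display and overlays
(matplotlib colormap, red = high). The attribution math is decoupled from
the network through a three-tuple protocol (logits, activations, gradients),
which is what lets analytic stub models verify the closed form in tests.

## Handcrafted baselines

Per image: 7 Hu moments of the grayscale image, signed-log transformed
(sign(h)·log10(|h|+ε)) because raw moments span many orders of magnitude;
GLCM contrast on a 32-level quantized, symmetric, normalized co-occurrence
matrix over distances {1, 2, 3} × orientations {0°, 45°, 90°, 135°}
(conventional Haralick grid, configurable); a 26-bin normalized histogram of
uniform LBP codes (R = 3, P = 24); and mean H, S, V with H ∈ [0, 1).
Features are z-scored with training-split statistics using the sample
standard deviation (n−1); constant columns map to 0. The four classical
classifiers are the scikit-learn implementations (GaussianNB,
DecisionTreeClassifier, SVC, KNeighborsClassifier) with library defaults and
pinned seeds — they are comparison plumbing, not a contribution — evaluated
on the same train/test partition as the CNN.

## Synthetic data generator

The generator emulates the structure of whole-plant phenotyping datasets:
C accessions × D dates × two viewpoints, filenames in the standard grammar.
Each "plant" is a noisy striped ellipse on a uniform dark background; the
accession index keys the hue and stripe frequency (scaled by `class_signal`
∈ [0, 1]; 0 makes classes identically distributed, 1 well-separated), the
date index drives a monotone increase in projected area ("growth"), and the
side view is a fixed affine squeeze-and-shear of the front renderer.
Per-pixel Gaussian noise (default sd 0.02 in [0, 1] units) is drawn from a
per-image seed stream, so outputs are byte-identical for a seed regardless
of rendering order. Defaults for the end-to-end experiments: 10 accessions,
5 dates, 96×128 px, seed 42, class_signal 1.0 — a deliberately separable
problem sized so that augmentation, 20-epoch training (CE and ACE), metrics
and Grad-CAM all run in minutes on one CPU.

What passing on this fixture shows: the augmentation enumeration and
bookkeeping are exact, the optimizer and losses behave as specified, the
metrics agree with independent oracles, and attention localizes on the
object that carries the class signal. What it does not show: performance on
real plants — real accessions differ far more subtly than synthetic hue
signatures, backgrounds and illumination vary, and the published real-data
accuracies additionally depend on ImageNet-pretrained backbones at
GPU scale, all outside this package's test envelope.

## Numerical choices and limitations

* float32 network arithmetic; determinism promised per machine, not across
  BLAS builds.
* mixgen rounds to nearest and clips to [0, 255]; at λ = 0.5 the operation
  is symmetric to within ±1 per pixel (rounding).
* Max-pool gradients share the gradient equally among tied maxima.
* Argmax ties (losses, predictions) break toward the lowest class index.
* GLCM on large images is O(H·W) per offset; feature extraction of big
  datasets is the baseline path's bottleneck.
* The `tiny` backbone requires input sides divisible by 8.
* No multi-device training, no mixed precision, no hyperparameter search.
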