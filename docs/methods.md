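# Methods

## Problem setting

A forward-view endoscopic OCT probe inside an epidural needle images the
tissue ahead of the tip as B-scans (width X × depth Z, 6.25 µm/pixel,
8-bit). During puncture the needle crosses fat, interspinous ligament and
ligamentum flavum before reaching the epidural space — a dark gap in front
of the needle, bounded below by the dura mater and spinal cord. The package
provides (i) tissue-layer recognition by a sequential cascade of binary
CNNs, (ii) regression of the needle-tip-to-dura distance once the epidural
space is reached, (iii) a subject-wise nested evaluation protocol, and
(iv) Grad-CAM explanations, all exercised end-to-end on a synthetic data
generator.

## Synthetic B-scan generator

Each tissue class is rendered from a small phenomenological appearance
model: a depth profile `surface_brightness · exp(−(z−z0)/attenuation_length)`
below a jittered surface row z0 (uniform 2–8 px, pressed tissue), modulated
by per-class texture terms — periodic transverse bands for the interspinous
ligament (thick fiber bundles), low-frequency lateral heterogeneity for fat
(adipocyte pockets) — multiplied by unit-mean gamma speckle, attenuated by
a depth roll-off `exp(−z/160 px)` (system sensitivity/defocus falloff: the
probe focuses at the lens tip, so structures seen across a deep gap are
dim), summed with an exponential noise floor, Gaussian-blurred (σ = 1 px,
point-spread), clipped and quantized to 8 bits. Epidural-space frames put
the tissue surface at `round(distance/6.25 µm)` rows deep, with pure noise
floor above.

Defaults satisfy the qualitative orderings of the real tissue types:
attenuation length ligament (110 px) > fat ≈ cord (55 px) > flavum
(22 px); flavum has the brightest surface (235); fat is far more laterally
heterogeneous than cord (0.40 vs 0.08). Per-subject variability multiplies
every appearance parameter by a log-normal factor (σ = 0.08–0.15), drawn
once per subject, so subject-grouped validation is meaningful. Epidural
distances are uniform over 0.2–2.5 mm. Classification frames are 181 × 241
px (width × depth) and can hold at most ~1.5 mm of gap; deeper gaps render
as frames of pure background — the dura lies beyond the imaging depth —
and the stored distance label saturates at the frame depth. Regression
frames are 241 × 681 px and hold the full range. A "confusable"
configuration sets fat's appearance equal to spinal cord's (up to residual
heterogeneity), reproducing the hard pair for a flat five-class model.

What the generator does **not** model: wave-optics speckle correlation,
probe motion, blood, histology-level microstructure, or any quantitative
match to real porcine image statistics. Passing tests therefore show the
pipeline's logic and learnability under the stated signatures, not
clinical performance.

## Classifiers

Training recipe (all tasks): SGD with Nesterov momentum, lr 0.01, momentum
0.9, decay 0.01, batch 32. The decay is the hyperbolic per-update schedule
lr/(1 + 0.01·t) with t counting batch updates (configurable to per-epoch);
per-update annealing matters for the non-vanishing sign gradients of the
MAPE objective below. Classification minimizes sparse categorical
cross-entropy with early stopping (patience 10, epoch cap 100 by default)
and restores the best-validation-epoch weights. Images are centered by
subtracting the training-set mean pixel (stored on the model) and scaled
by 1/255.

Architecture names denote compact re-implementations built from each
family's signature block — plain conv stacks ("small-cnn"), skip
connections ("resnet50-like"), parallel multi-scale branches
("inception-like"), depthwise-separable convolutions ("xception-like") —
at widths that keep the full nested protocol tractable on one CPU. All
classification variants share three design elements beyond the conv
stack:

* **batch normalization** after every conv/block (as in the full-size
  originals); without it channel magnitudes are unbounded and dominate
  any channel-weighted saliency;
* **a depth-coordinate input channel** (CoordConv style): with receptive
  fields of only ~25 px, the stacks otherwise cannot distinguish "dark
  near the needle tip" from "dark at depth", and depth position is exactly
  what separates an epidural gap from attenuated deep tissue;
* **a fixed gap-map side branch**: per column, the image is box-smoothed
  along depth, contrast-normalized, reduced to its causal cumulative-max
  envelope and rectified at a bank of thresholds — a parameter-free map of
  "dark region above the first bright structure", the clinical signature
  of the epidural space. The branch is spatially aligned with the learned
  stack by fixed box-pooling and concatenated to the final feature maps;
  the dense head learns its weights like any other channel.

The head is concatenated global average + max pooling into a dense output
layer (softmax): the averaged half carries texture/attenuation statistics,
the max half turns spatially localized channels into existence detectors.

## Distance regressor

The distance signal lives entirely in the depth profile, so the regression
variants collapse the lateral axis first (mean over X), box-smooth along
depth, contrast-normalize per frame (speckle amplitude varies between
frames and subjects), and take the causal cumulative-max envelope — a
monotone curve stepping from background level to 1 at the dura surface.
This fixed front end is non-trainable: frozen, it preserves the envelope's
scale, and a trainable version destabilized the fixed lr-0.01 recipe by
exploding through the normalization. Behind it, each architecture family
contributes a trainable stack (1×1 threshold bank for "small-cnn",
residual / inception-style / separable depth-wise blocks for the others)
whose global-average-pooled features count the envelope's
threshold-crossing depth, followed by the single identity-activation
output neuron.

Regression trains for a fixed 20 epochs under a MAPE objective. Numerical
conditioning choices: targets are internally scaled to units of 100 µm so
the fixed learning rate is neither divergent (µm/1000 scale oscillates)
nor stagnant (raw µm barely moves); the output layer starts as the
unbiased constant predictor (zero weights, bias at the mean training
distance). The public API always speaks µm.

The analytic surface detector (`detect_surface_distance`) is the
non-learned baseline and labeling oracle: lateral mean per row, 3-sample
box smoothing, background = 10th percentile of the smoothed profile,
surface = first row exceeding background + 0.2·(peak − background);
distance = row × 6.25 µm. Frames whose peak clears the background by less
than 15 counts raise a "no surface found" error. The point-spread blur
pulls the detected row one pixel early on bright surfaces, within the
one-pixel tolerance used throughout.

## Cascade state machine

One binary classifier is active at a time. The state tracks the most
recent ≤ 50 hard predictions of the active stage; the displayed fraction
is class-1 count over min(frames seen, 50), colored green below 26 class-1
hits, yellow from 26 and red from 35. Reaching 35 switches to the next
classifier (stage 4 never switches and displays no fraction). The window
is cleared on switch — the new classifier's outputs are incommensurable
with the old window (configurable off) — and a switch may fire before 50
frames accumulate, which is conservative (35 of fewer is stricter).
Switch events are logged with 1-based global frame indices.

## Nested evaluation

With n subjects, the outer loop rotates each subject through the test
role; the inner loop rotates each remaining subject through validation
while the others train (8 subjects → 8 × 7 rotations). Every candidate
architecture is trained in every inner rotation; selection takes the best
mean inner metric (accuracy maximized for classification, MAPE minimized
for regression; exact ties go to input order). The selected architecture
is retrained on the cross-validation subjects — for classification one CV
subject stays out as the early-stopping validation set, for regression
(fixed epoch budget, no early stopping) all CV subjects train — and is
scored once on the held-out test subject. A leakage audit asserts
subject-set disjointness before every training run and aborts on
violation. Per-fold metrics aggregate as mean ± standard error (sample SD
/ √n; a single fold reports SE 0 and is flagged). Run seeds derive from a
base seed offset by fold and architecture indices.

## Grad-CAM

The saliency target is the deepest layer whose output keeps spatial
extent > 1×1 (for the classification nets, the concatenated learned +
gap-map feature block). The score is the softmax output of the target
class, as in standard Keras usage, so competing-class evidence enters
negatively; because the heatmap is max-normalized, the positive scalar
p·(1−p) prefactor of the softmax gradient is dropped and the gradient
direction unit-normalized in float64 — otherwise a saturated softmax
underflows to an all-zero gradient and a spurious empty map. Channel
weights are the spatially pooled gradients; the weighted channel sum is
rectified at zero, bilinearly upsampled to the input grid and normalized
by its maximum. An identically zero gradient yields an all-zero map
(documented fallback). Regression models are rejected.

## Numerical and scope notes

* Determinism: every entry point takes an explicit seed; identical seeds
  give bit-identical synthetic data and training trajectories.
* The backprop engine is float32 with an im2col convolution; gradient
  correctness is verified against central finite differences in the test
  suite (kink points of ReLU/max excluded).
* Problem sizes in the test and acceptance runs are scaled-down study
  conditions chosen for single-CPU tractability: 200 frames/class/subject
  and a 6-epoch cap for the stage classifiers, 300 epidural
  frames/subject for the regressor, 120 frames/class/subject over 4
  subjects for the confusable-configuration comparison.
* Known limitations: no attempt to reproduce real-data accuracies or the
  full-size Keras architectures; no temporal smoothing of the video
  stream; the external-deposit directory adapter is best-effort and
  optional.
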