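# Methods

`phroot` reimplements, as one importable package with a thin CLI, the
quantitative core of a deep-learning pipeline for apoplastic-pH analysis in
confocal images of *Arabidopsis thaliana* root tips: semantic segmentation
of developmental zones with a deterministically trained U-Net², epistemic
uncertainty via Monte Carlo Dropout, attribution via Guided Grad-CAM, and
ratiometric HPTS 458/405 statistics with Welch's t-tests.

## Image model and classes

Inputs are 4-channel 2-D images in OME-TIFF (or plain multi-page TIFF with
the conventional page order): (1) fluorescence at 405 nm excitation
(protonated HPTS), (2) brightfield at 405 nm, (3) fluorescence at 458 nm
(deprotonated HPTS), (4) brightfield at 458 nm.  The default physical pixel
size is 0.415133 µm.  Segmentation masks label each pixel background (0),
root tissue (1), EEZ (2), LEZ (3) or MZ (4).  Zones are defined
morphologically by the cell length/width ratio: MZ < 1, EEZ within [1, 2],
LEZ > 2.

## Network

The segmentation model is the nested residual-U-block encoder–decoder
(U-Net²): six encoder stages (RSU-7/6/5/4 and two dilated RSU-4F blocks),
five decoder stages, per-stage 3×3 side-output convolutions upsampled to
input size, and a 1×1 fusion convolution — adapted to one brightfield input
channel and five classes.  Each convolution is 3×3 (dilated where the block
design says so), followed by batch normalization and ReLU.

Normalization layers carry **no learnable affine parameters**: with plain
convolution weights and biases the full-scale preset has exactly
**44,035,385 trainable parameters (44.04 M)**.  This choice is the package's
reconstruction of the published count — with affine batch norm the same
layer plan gives 44,064,185 (44.06 M) — and `phroot.model.parameter_table`
prints the per-parameter breakdown for audit.  A reduced `"tiny"` preset
(three encoder stages of RSU-4/RSU-4F blocks, widths 8–16, 24,615
parameters) keeps the exact block topology for desk-scale training and
tests.

Ceil-mode 2×2 max pooling plus size-matched bilinear upsampling lets the
network process any input size without padding, so tests run at 64–96 px
while the acquisition format is 512 px.  Input images are min–max
normalized to [0, 1] per image.  Argmax ties in prediction break toward the
lowest class index (background).  Each convolution is preceded by a dropout
slot that is inactive except under Monte Carlo Dropout.

The compute core is a minimal reverse-mode autodiff engine on numpy arrays
(`phroot.nn`), providing exactly the primitives the model needs; every
primitive's backward pass is validated against central finite differences
in the test suite.  Being pure numpy, seeded runs are bit-exact
reproducible by construction.

## Training

- Split: lexicographically sorted ids, seeded shuffle, floor(n·f) blocks
  for (0.8, 0.1, 0.1); remainder ids go to the training set (601 ids →
  481/60/60).
- Augmentation: rotation up to 10°, shift up to 26 px, and a scale change
  of up to 51 px of linear size, each applied with probability 0.5; one
  combined affine (rotate, then shift, then scale about the center) warps
  the image bilinearly and the mask nearest-neighbour.  The resampling
  order is a fixed, documented choice.
- Loss: focal loss, mean over pixels of −(1−p_t)^γ·log p_t with γ = 2 and
  an ε = 1e-8 floor inside the log; γ = 0 recovers cross-entropy.  The loss
  is applied to the fused output (side outputs are not separately
  supervised — a simplification adequate at desk scale and documented
  here).
- Optimizer: Adam, default learning rate 1e-3, deterministic update order.
- Model selection: highest validation mean IoU over the specialized
  classes EEZ/LEZ/MZ (the classes that matter downstream); per-class IoU on
  images where the class union is empty is excluded from that class's mean.
  Both the specialized three-class average and the all-class average are
  reported, since "average IoU" is ambiguous between the two.
- Determinism: with the flag set, shuffling and augmentation draw from
  substreams of one seed and runs are bit-exact; unseeded runs draw OS
  entropy and show nonzero run-to-run parameter variance.

The reference experiment at full scale (601 images, 74 epochs, 10
repetitions) is reproduced in scaled-down form: 16 synthetic 64-px images,
3 epochs, ≥3 runs, zero parameter-wise standard deviation across runs.
Desk-scale learning capability is demonstrated on 100 synthetic 96-px
images, where the tiny preset exceeds 0.8 validation mean IoU within ~20
epochs; the published full-scale IoU (0.75 on real data) requires the real
dataset and full-scale training and is outside this package's test scope.

## Uncertainty

Monte Carlo Dropout with dropout before every convolution, rate 0.5, T = 10
passes (all configurable).  The per-class uncertainty is the standard
deviation of the softmax outputs across passes with divisor T (the Monte
Carlo moment estimate); it is bounded by 0.5 because softmax outputs live
in [0, 1].  The mean softmax across passes estimates the predictive
distribution.  The single displayed map is the std of the probability of
the per-pixel predicted class (argmax of the mean softmax) — the 5-map→1-map
reduction is this package's documented choice; per-class maps are always
retained.  Dropout sampling uses its own seeded generator, independent of
training seeds.  Zero rate or T = 1 gives identically zero maps; pixels
whose samples are bit-identical across passes are assigned exactly zero
spread rather than the float32 rounding residue of the mean.

## Attribution

The class score is Σ of the target class's fused logits over pixels whose
argmax equals the target class; a class with no predicted pixels has score
0 and an identically zero attribution.  Guided Backpropagation is the input
gradient of this score with negative upstream gradients blocked at every
ReLU.  Grad-CAM weighs the chosen layer's activations by their spatially
averaged score gradients, rectifies the weighted sum and upsamples
bilinearly; the default layer is the last convolution of the final decoder
stage (`de1.conv1d`), the highest-resolution semantic feature map, and is
configurable by name.  Guided Grad-CAM is the elementwise product.  Report
panels show the top-3 most frequently predicted non-background classes;
maps are normalized per image for display only, raw values are exported.

## Ratiometrics

X = fl458/fl405 per pixel; pixels with fl405 ≤ ε are invalid (ε = 0 by
default, i.e. any strictly positive denominator counts, configurable).
Zone mean = Σ(X⊙Y)/ΣY over **valid** zone pixels — invalid pixels are
excluded from both sums rather than counted as zeros, which would bias
means downward.  Welch's t-test (scipy, unequal variances,
Welch–Satterthwaite df, two-sided p) compares per-sample zone means between
groups; default contrasts are mock-vs-BL within each line and line-vs-Col-0
within each treatment.  Quartiles use linear interpolation.  No
multiple-testing correction is applied; the report flags that several zones
and contrasts are tested.

## Synthetic data

The generator defines the study conditions for all tests: a gently curved
root band (random low-order polynomial centerline) entering from the top of
the frame with its tip near the bottom; zone spans along the axis (root
cap, then MZ, EEZ, LEZ, generic root above); per-zone cell grids drawn as
dark borders on bright interiors in both brightfield channels, with cell
length/width ranges respecting the morphological rules.  The 405 nm
fluorescence is a flat base intensity (20,000 counts inside the root) and
the 458 nm channel is base × zone ratio × multiplicative Gaussian noise
(default sd 0.05, on the 458 channel).  Default true ratios: MZ 1.5, EEZ
2.0, LEZ 2.5, generic root 1.8.  The treatment effect is multiplicative
(default 0.8, i.e. a 20% acidification-like drop) and applies only to
wildtype + BL, emulating the receptor-dependent response.  Intensities are
stored as 16 bit; the base intensity is chosen so default ratio values are
exactly representable, hence noise-free zone means recover configured
ratios exactly.

What the generator does **not** emulate: optics (PSF, depth effects),
within-zone pH heterogeneity, cell-to-cell intensity variation, sample-level
biological variability beyond pixel noise, or 3-D structure.  Passing tests
therefore demonstrate the correctness of the computational machinery under
the stated statistical structure, not segmentation performance on real
micrographs.

A recovery simulation (tiny model trained to ≥0.8 validation IoU on 100
synthetic 96-px images, then applied to a fresh 40-sample study at noise sd
0.05) established the tolerance for predicted-mask zone-mean recovery used
in the acceptance suite: relative errors average under 2% (95th percentile
≈ 4%, worst case ≈ 6%), dominated by boundary-pixel contamination from
adjacent zones rather than by noise; the frozen bounds are 8% per measure
and 3% on the mean error.
With n = 10 per group the wildtype mock-vs-BL contrast is significant in
every specialized zone and the mutant contrast is null; being a true null,
its p-value is uniform, so a given seed has the nominal 5% chance of a
spurious rejection.

## Problem sizes

Tests and examples use 64–96 px images, the tiny preset, ≤22 epochs, and
T ≤ 10 dropout passes — sizes chosen so the whole suite runs comfortably on
a single CPU while still exercising every code path of the full-scale
configuration (which differs only in preset widths and input size).

## Determinism of outputs

Result OME-TIFFs embed a content-derived UUID instead of a random one, and
CSV floats are written with a fixed format, so repeated runs with one seed
produce byte-identical measures/comparisons CSVs and image files.  Result
stacks are written as a single float32 series (labels 0–4 are exactly
representable); synthetic datasets keep native uint16 with the mask as a
fifth channel.

## Known limitations

- The full-scale preset trains only in principle on this numpy engine;
  training it to the published performance needs the real dataset and is
  computationally out of scope here.
- CZI input is not supported (convert to OME-TIFF upstream); OMERO/ROI
  workflows are out of scope — masks are consumed directly.
- Aleatoric uncertainty, deep ensembles, calibration curves, and
  attribution families beyond Guided Grad-CAM are not implemented.
- Ratio-to-pH calibration is not part of the pipeline output.
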