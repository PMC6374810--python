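# Methods

## Problem

Automatic volumetric segmentation of a single tumor in anisotropic
T2-weighted MR volumes, cast as per-voxel binary classification followed
by a geometric refinement of the resulting boundary.  Because real
patient data of this kind is restricted, the package substitutes a
synthetic phantom generator with known ground truth for every empirical
exercise; no claim in this repository is based on patient data.

## Network

The model is a dual-path, multiscale, densely connected 3D CNN.

* An initial 3×3×3 convolution lifts the single input channel to
  `initial_channels` (reference: 16) feature maps.
* The **depth path** (scale s1) runs at full resolution:
  `depth_layers` = 8 transformation layers, each BN → ReLU → 3×3×3
  convolution emitting `growth_rate` (reference: 12) channels → dropout
  (rate 0.2).  Dense connectivity: layer *l* consumes the initial map
  concatenated with all previous s1 outputs, i.e. `c0 + (l−1)k` input
  channels.
* The **scaled path** (s2) runs at half resolution (2×2×2 max pooling):
  `scaled_layers` = 9 transformation layers.  Besides the pooled initial
  map and all previous s2 outputs, layer *l* receives stride-2 pooled
  copies of the s1 outputs up to layer *l* (**diagonal connections**), so
  its input width is `c0 + (l−1)k + min(l, 8)·k`.  These closed forms are
  exported as `expected_channels` and verified against built networks.
* Only the scaled path feeds the classifier.  The decoder is
  BN → ReLU → 1×1×1 compression (reference: 128 channels) → 2×2×2
  transposed convolution, stride 2 (reference: 64 channels) → BN → ReLU →
  3×3×3 convolution (64 → 64) → dropout → 1×1×1 classifier with bias to
  2 classes, softmax over channels.

With the reference configuration the network has **716 586 trainable
parameters** (≈ 0.72 M), counted over all convolution kernels, the
classifier bias and BN scale/shift pairs.

## Numerics

No GPU framework is used.  All layers run on a small NumPy
reverse-mode autodiff engine (`msdseg.nn`): tensors carry backward
closures, gradients flow through a topologically sorted graph, and every
operator's backward pass is validated against central finite differences
in the test suite.  3D convolutions are computed by a padded-grid
shift-and-GEMM scheme with two GEMM layouts chosen per call by a cost
heuristic.  Batch statistics for BN are accumulated in float32 (pairwise
summation), running statistics in float64.

## Training recipe

SGD with momentum 0.05 and weight decay 5e-4; base learning rate 0.05
decayed by the poly policy `lr = 0.05·(1 − t/T)^0.9` (a step policy,
divide by 10 every 50 epochs, is available behind a config switch);
weights initialized i.i.d. N(0, 0.01²); 32³ subvolumes sampled with
probability 0.5 centered on a foreground voxel, otherwise uniformly;
with probability 0.5 a patch is rotated in-slice by 90°, 180° or 270°;
loss is softmax cross-entropy in nats per voxel.  The reference schedule
is 40 000 iterations at batch size 4; desk-scale runs shrink the
iteration count, patch size and network widths but keep the recipe.

## Inference

A volume is tiled by overlapping fixed-size patches on a stride grid
(boundary patches clamped inside).  Per voxel, the hard labels of all
covering patches are fused by strict majority vote, with exact ties
broken by the mean foreground probability; the probability output is the
arithmetic mean over covering patches.  Odd volume dimensions are
zero-padded to even and cropped back.

## Level-set refinement

The fused probability map `P` seeds a geodesic-active-contour evolution.
`g` is `P` smoothed by a 1 mm Gaussian and rescaled to [0, 1]; the speed
fields are `X = −∇g` (advection toward the probability edge) and
`Y = Z = g`.  φ is the signed Euclidean distance (negative inside, mm,
spacing-aware) of the 0.5-thresholded region, evolved by

    φ_t = α·X·∇φ(upwind) − F|∇φ|(Godunov, F = −β·Y) + γ·Z·κ|∇φ|

with α = 1, β = −0.5 (negative ⇒ outward propagation), γ = 1, an explicit
scheme with CFL-limited time step (safety 0.4), reinitialization to a
signed distance every 10 iterations, and a 50-iteration cap.  κ is mean
curvature by central differences (2/r for a sphere of radius r).

## Metrics

* DSC = 2TP / (FP + 2TP + FN); both masks empty ⇒ 1.
* RR (recall) = TP / (TP + FN); undefined (error) for empty ground truth.
* ASD: boundary voxels are foreground voxels removed by one 6-connected
  erosion (volume border counts as background); ASD is the symmetrized
  mean over both boundaries of the minimum Euclidean distance (mm,
  spacing-aware) to the other boundary.

Case tables report per-case values plus mean and sample-SD rows.

## Phantom generator (scope)

One tumor per volume: an ellipsoid (in-plane semi-axes 5–9 mm, axial
8–14 mm) whose in-plane radius is modulated per slice by a 3-lobe
sinusoid (amplitude 0.25) with drifting phase, guaranteeing a single
6-connected component with slice-to-slice cross-section variation.
Intensities: smooth Gaussian-filtered textures (background 100 ± 20,
tumor 150 ± 15, arbitrary units), a low-order polynomial multiplicative
bias field (±20 %), additive Gaussian noise (SD 10), voxels
0.6 × 0.6 × 1.2 mm on a 64 × 64 × 48 grid.  The intensity distributions
deliberately overlap — in strongly biased regions background can reach
tumor-like brightness — so the segmentation task is not solvable by
thresholding.  The generator also produces degraded probability maps
(blur + noise of a ground-truth mask) as fixtures for the level-set
refinement.

## Limitations

* All empirical statements are desk-scale and phantom-based; none of the
  patient-data results of the emulated study design are reproduced here.
* The NumPy engine is single-threaded and CPU-bound; reference-scale
  training (40 000 iterations, 32³ patches) is far outside its intended
  use.
* The phantom models one tumor with smooth texture; it does not emulate
  organ boundaries, motion artifacts or multi-focal disease.
* The level-set scheme is explicit; its cost grows with volume size and
  iteration count, and the CFL-derived step can be small for strongly
  peaked speed fields.
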