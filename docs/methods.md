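# Methods

## Problem

Cerebral microbleeds (CMBs) are small (≈2–10 mm) hemosiderin deposits that
appear as round hypointense foci on susceptibility-sensitive MRI (T2*-GRE,
SWI).  They are biomarkers of small-vessel disease and the hemorrhagic type
of amyloid-related imaging abnormalities (ARIA-H); anti-amyloid trial
protocols gate treatment eligibility on the per-subject CMB count binned
into the intervals 0, 1–4, 5–9, ≥10.  Automated detection is hard because
veins and calcifications look locally identical to CMBs: single-stage
segmentation networks propagate those confounders through their skip
connections and trade precision against recall.

`cmbseg` implements a single-stage answer to that problem: a U-Net whose
encoder uses residual large-kernel (RLK) blocks to capture enough spatial
context to tell a sphere from a tube, and whose skip connections are
filtered by convolutional block attention (CBAM) plus additive attention
gates before fusion into the decoder.

## Network

* **Input.**  Three-channel 2-D slices: the target axial slice stacked with
  its immediate neighbours (edge slices replicate).  2-D slice models with
  a thin 3-D context are robust to the large slice-thickness variation
  across scanners; H and W must be divisible by 8.
* **Encoder.**  Four stages of RLK blocks
  `x + droppath(conv_k×k → GroupNorm → GELU → conv_1×1)` with k = 13 by
  default; stride-2 3×3 convolutions downsample between stages.  Stochastic
  depth rates grow linearly to 0.1 across stages (0 everywhere in the tiny
  profile, where runs are too short for it to act as regularization).
* **Skip connections.**  Each of the three skips passes through CBAM —
  channel attention `σ(MLP(avgpool F) + MLP(maxpool F))` with a shared
  bottleneck perceptron (reduction 16), then spatial attention
  `σ(conv_7×7([avg_c F′ ; max_c F′]))` — followed by an additive attention
  gate conditioned on the coarser decoder feature.  CBAM and the gate are
  composed serially (CBAM first) for determinism; every attention
  coefficient lies strictly in (0, 1).  CBAM can be switched off per skip
  for ablations.
* **Decoder & deep supervision.**  Bilinear ×2 upsampling + 3×3
  convolution, concatenation with the gated skip, and a refinement
  convolution.  1×1 heads emit a full-resolution logit map plus three
  auxiliary maps at 1/2, 1/4 and 1/8 resolution (the last from the
  bottleneck).  Head biases initialize at −4 logits, encoding the strong
  background prior of sparse lesions.

Widths default to (32, 64, 128, 256) ("paper" profile) and (8, 16, 32, 32)
("tiny" profile).  The parameter count is a pure function of the
configuration and is printed by `cmbseg summary`.

### Numerical engine

The network, backpropagation, and optimizer are implemented directly over
NumPy in float32.  Stride-1 convolutions of kernel ≥ 3 run in the FFT
domain (cost independent of kernel size, which is what makes 13×13 kernels
affordable on a CPU); the forward spectra are cached and reused by the
backward pass, whose input-gradient is the exact adjoint (a phase twist on
the output-gradient spectrum times the conjugate kernel spectrum) and whose
weight-gradient is a wrap-free circular correlation.  Strided and 1×1
convolutions use im2col + GEMM.  Bilinear ×2 up/down-sampling is expressed
as fixed interpolation matrices, so its backward is an exact transpose.
Every backward pass (including GroupNorm, GELU, CBAM's shared-MLP and
argmax-scatter paths, attention gates, and the full composite network) is
verified against central finite differences in the test suite; because
channel/spatial max-pooling introduces kinks, those checks use ε = 1e-4
steps and tolerate the float32 noise floor.

## Objective

Per output k: `L_k = Dice + Focal`, with

* Dice `1 − (2Σp·g + ε)/(Σp + Σg + ε)`, ε = 1e-5: overlap-based and immune
  to the foreground/background imbalance (lesions occupy ~10⁻³ of a slice);
* Focal `mean(−α(1−p_t)^γ log p_t)`, γ = 2, α = 0.25, probabilities
  clamped to [1e-7, 1−1e-7]: down-weights easy background voxels.  α is a
  single constant applied to every voxel, so γ = 0, α = 1 reduces exactly
  to mean binary cross-entropy.

Total: `Σ_k λ_k (Dice_k + Focal_k)` with λ = (0.4, 0.3, 0.2, 0.1) ordered
final → deepest.  Auxiliary targets are built by repeated 2×2 max-pooling —
average pooling would erase single-voxel lesions.  Dice and Focal are
computed per slice and averaged over the batch.

## Training protocol

AdamW (decoupled weight decay 0.01; 1e-4 in the tiny profile).  Learning
rate: linear warmup 1e-7 → 1e-4 over 10 epochs, then cosine annealing with
warm restarts (first cycle 50 epochs, period ×2, floor 1e-6).  The tiny
profile compresses this to warmup 1e-7 → 1e-2 over 1 epoch and a single
11-epoch cosine cycle over 12 epochs total.  No early stopping; within each
fold the checkpoint with the highest validation lesion-level F1 is retained,
using the same lesion-matching protocol as the final evaluation so model
selection and reporting cannot diverge.  The per-epoch sampler takes every
lesion-bearing slice plus an equal number of freshly drawn lesion-free
slices; zero-CMB subjects are not required.  Cross-validation partitions
subjects (never slices) into k folds.

Augmentation (±15° rotations with bilinear/nearest interpolation for
image/mask, horizontal/vertical flips, lesion-centered crop jittered by up
to 25 % of the window, and a monotone cubic-bezier intensity distortion
with sorted interior control points drawn uniformly in [0,1]²) is on by
default but off in the tiny profile: each phantom subject already carries
freshly generated anatomy, and at 12-epoch budgets augmentation slows
convergence without measurable benefit there.

## Evaluation

* **Lesion extraction.**  Probability maps thresholded at 0.5; connected
  components with 26-connectivity in 3-D (one microbleed spanning several
  slices counts once) or 8-connectivity per slice in 2-D mode; components
  under 2 voxels are discarded as specks.  Equivalent diameter is that of
  the equal-volume sphere (2·(3V/4π)^⅓, V in mm³ from the header spacing).
* **Matching.**  Greedy one-to-one pairing in ascending centroid distance,
  ties broken by lower predicted id; a pair requires distance ≤ 4 voxels
  (inclusive; distances in voxel index units).  Unmatched predictions are
  FPs, unmatched ground truths FNs; TP+FN = |GT| and TP+FP = |pred| always.
  Greedy matching is equivalent to the exhaustive optimal assignment
  whenever distinct true lesions are separated by more than twice the match
  radius — the regime the centroid rule presumes; when two true lesions sit
  within 8 voxels of each other the assignment itself is ambiguous and
  greedy is the defined tie-break.
* **Metrics.**  Micro-averaged precision/recall/F1 over pooled TP/FP/FN;
  FP_avg = pooled FP / number of subjects (lesion-free subjects count in
  the denominator).  Zero-denominator conventions: precision = 1 with no
  predictions, recall = 1 with no ground truth.  The ≤3 mm stratum
  recomputes the metrics with ground truth restricted to small lesions;
  predictions that the full matching paired to an excluded large lesion are
  dropped from the pool rather than counted as FPs.
* **Burden.**  Per-subject predicted vs true counts are binned into the
  ARIA-H intervals (0, 1–4, 5–9, ≥10), accumulated into a 4×4 confusion
  matrix (GT rows), and correlated by Spearman's ρ (average ranks for
  ties) with a 95 % Fisher-z interval `tanh(atanh ρ ± 1.96/√(n−3))`,
  omitted with a warning for n < 4.
* **Grad-CAM.**  At a chosen decoder stage, channel weights are the
  spatially averaged gradients of the summed positive-region logits; the
  CAM is the ReLU-rectified weighted activation sum, upsampled and
  normalized to [0, 1].

## Phantom generator

The phantom emulates the *detection problem*, not MR physics: an
ellipsoidal brain (per-axis radii 0.8× the half-extent) of unit intensity
containing

* `n_cmb` hypointense spheres (diameters uniform in `cmb_diameter_range`,
  default 2–10 mm; intensity 30–60 % of background; sub-voxel centers,
  rasterized by a center-inside test; mutually separated by ≥1 mm of
  clearance) — these and only these enter the ground-truth mask and lesion
  table (rasterized-voxel-mean centroid, planted diameter);
* `n_vessels` dark tubes (random polylines, 3–5 segments of 8–15 mm total,
  radius 0.5–1 mm, same 30–60 % intensity band, kept clear of the planted
  spheres) — never in the mask;
* `n_calcifications` small faint blobs (1–1.8 mm, 70–85 % intensity) —
  never in the mask;
* a multiplicative quadratic-polynomial bias field (peak fraction
  `bias_field_amplitude`) and additive Gaussian noise (`noise_sigma`, in
  background-intensity units) inside the brain.

Everything derives from the spec's seed, so generation is bit-reproducible.
What the phantom does **not** model: susceptibility blooming and phase
effects, anatomy (no atlas), partial-volume fading at lesion rims, motion
and flow artifacts, multi-scanner contrast families.  Passing desk-scale
tests therefore demonstrates that the architecture, losses, training loop
and evaluation protocol work end-to-end and that attention filtering can
suppress elongated confounders — not clinical-grade performance on real
SWI.

## Desk-scale study conditions

The end-to-end acceptance experiment uses: phantom volumes (10, 64, 64) at
1 mm isotropic; 1–3 CMBs per subject with diameters 2.5–4.5 mm; 3 vessels
and 2 calcifications per subject; noise σ = 0.08; bias amplitude 0.15;
40 training subjects (34 train / 6 validation) and 12 held-out test
subjects; the tiny network (≈460 k parameters, 13×13 kernels) trained for
12 epochs at batch 16.  Three seed-paired CBAM-enabled/disabled twins are
trained on identical data; the CBAM-disabled twin is read at threshold
0.5 and the CBAM twin at the sweep threshold (0.3–0.7) with the lowest
FP_avg among those reaching at least the twin's recall.  These sizes were
chosen so the whole experiment (six trainings plus evaluation) completes
in minutes on one CPU core while leaving the detection task non-trivial —
vessel cross-sections overlap the microbleed intensity range exactly.

## Known limitations

* The FFT convolution assumes "same" padding with odd kernels; no dilation
  or grouped convolution.
* Droppath keeps per-sample granularity but the tiny profile disables it;
  the 1000-epoch paper profile is configured but not exercised in CI-scale
  runs.
* The 2-D connected-component mode and the 3-D default can give different
  subject-level counts for lesions spanning slices; 3-D merge is the
  default everywhere.
* Bias-field correction and skull stripping are out of scope: input is
  assumed skull-stripped (nonzero brain on zero background), as the
  phantom guarantees by construction.  External N4ITK/BET pre-hooks can be
  run before `cmbseg preprocess`.
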