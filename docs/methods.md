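# Methods

## Model

The package implements a joint model for two coupled tasks on
single-channel T2-FLAIR-like brain volumes: voxelwise lesion segmentation
and per-case disease classification (0 = MS, 1 = NMOSD). The premise is
that the two tasks share their evidence — lesions' local appearance and
their global spatial distribution — so a shared encoder plus explicit
cross-task interactions should outperform two independent networks trained
on the same limited data.

**Information sharing.** The trunk is a dual-branch encoder. The local
branch applies layer normalization to the input and three 3×3×3
convolutions (strides 2, 1, 1), producing `C` channels at half resolution.
The global branch embeds the volume into a /16 token grid (8×8×8 stride-8
convolution followed by 2×2×2 average pooling), layer-normalizes, applies
two windowed self-attention layers (window 5³, 4 heads, MLP ratio 4,
relative position bias; the second layer cyclically shifts the window
partition) and trilinearly upsamples to half resolution. A cross-stitch
unit with four learnable scalars linearly mixes the branches into the two
task features `f_seg` and `f_cls`; it is initialized to the identity
mixing (`w_seg,1 = w_cls,1 = 1`, `w_seg,2 = w_cls,2 = 0`) so training
starts from unmixed branches. At the full-scale configuration (160³ input,
C = 32) both features are 32 × 80³.

Two windowed-attention simplifications: windows larger than the token grid
are clipped to the grid (needed at desk scale, where the grid is 2³), and
the shifted layer omits the boundary attention mask, i.e. wrapped
neighborhoods created by the cyclic shift may attend to each other. The
MLP uses ReLU. These choices affect no shape contract and are invisible at
the window/grid combinations used here.

**Segmentation.** A U-shaped head over `f_seg`: three encoder blocks with
two stride-2 downsamplings (C → 2C → 4C), then three decoder blocks with
three trilinear upsamplings and channel concatenation skips. Each block is
two (conv3³ → instance norm → ReLU) layers; instance normalization is used
because the training batch size of 2 makes batch statistics unreliable.
Four single-channel 1×1×1 heads read the decoder features at scales L/8,
L/4, L/2 and L, are nearest-neighbor upsampled to full resolution, fused
with fixed weights α = (0.25, 0.25, 0.5, 1) and passed through a sigmoid.
The three sub-full-scale sigmoid maps are retained as `S_i` for the
cross-task loss. Binarization threshold at inference: 0.5 (configurable).

**Lesion guidance.** The full LGM derives a voxelwise attention map
`sigmoid(conv3³s2(P))` from the lesion probability map, gates `f_cls` with
it, and fuses the gated features with a downsampled copy of `P` through
stride-2 3×3×3 convolutions and a 1×1×1 channel-reduction. With stride-2
fusion convolutions the joint features sit at quarter resolution (40³ at
full scale); a stride-1 option is available. The attention nonlinearity is
sigmoid — independent voxelwise gates — with a softmax-over-voxels option.
Ablation variants: `dot_product` (gating only), `concat` (concatenation
only, no gating), `dot_add` (probability map broadcast-added), `off`
(bypass).

**Classification.** Three residual stages (stride-2 stem conv + residual
block; 64/128/256 channels at full scale) with global average pooling
after each stage; the three pooled vectors are concatenated (length 448 at
full scale) into a single fully connected layer and a softmax. Keeping the
per-stage pooled vectors and the final-layer weights makes the
class-activation maps `V_i = Σ_k F_i,k · w^c_i,k` exact by construction.

**Objectives.** `L = β₁·L_seg + β₂·L_cls + β₃·L_cross`, β = (1, 0.8, 1).
`L_seg` is soft Dice with smoothing constant 1.0 in numerator and
denominator (configurable; at 0 the loss is exactly 1 − DSC). `L_cls` is
mean binary cross-entropy on the positive-class probability, clipped to
[1e-7, 1−1e-7] before the log. `L_cross` pairs each `S_i` with the CAM map
`V_i` of the true class: `V_i` is trilinearly resampled to `S_i`'s grid,
both are min–max normalized to [0, 1] (a constant map normalizes to
zeros), and the squared difference is averaged over voxels before the
η-weighting (η = 0.25, 0.25, 0.5). The mean — not the sum — keeps the
three scales commensurate; a voxel sum would let the largest grid dominate
regardless of η. `S_i` enter post-sigmoid.

## Training protocol

Adam with default moments, batch size 2, initial learning rate 1e-4,
200 epochs at full scale; the learning rate halves when the monitored loss
(training total loss by default; validation optional) fails to improve for
10 consecutive epochs. Training-time augmentation only: with probability
0.5 a flip along one uniformly chosen axis, and independently with
probability 0.5 a rotation (90°-multiples about a random axis by default,
so masks stay exactly binary; free-angle rotation with nearest-neighbor
mask resampling is available). Evaluation uses stratified k-fold
cross-validation (k = 5 by default) with per-fold reports averaged
unweighted; the fold split depends only on sorted case ids and the seed,
never on input order, and an optional group key keeps longitudinal
sessions of one patient in a single fold (off by default).

**Desk scale profile.** All experiments in the test suite run a reduced
instantiation: 32³ grid, 8 shared channels, 16/32/64 classification
channels, 2-fold CV, 30 epochs — a few hundred optimizer steps. Two
numerical choices make that budget workable: (1) the segmentation head
biases are initialized to −1 (fused logit ≈ −2, initial foreground
probability ≈ 0.12), the standard rare-foreground initialization for Dice
training — starting from p = 0.5 spends most of the early gradient budget
deflating the background; (2) the desk profile raises the initial learning
rate to 3e-3. Diagnostics behind that value: at 1e-3 the Dice loss is
essentially flat after 450 steps, at 4e-3 the classification head
destabilizes, at 3e-3 both tasks train. The full-scale profile keeps the
protocol's 1e-4.

## Synthetic phantoms

`synthetic_data` generates the two study conditions: an ellipsoidal
"brain" of intensity 1 on a zero background, lesions stamped as rotated
ellipsoids of intensity +1, additive Gaussian noise (SD 0.1), and the mask
defined exactly as the union of the stamped ellipsoids. Class 0 (MS-like)
draws 6–10 lesions of radius 1.5–2.2 voxels at high spatial dispersion
(0.85); class 1 (NMOSD-like) draws 1–2 lesions of radius 3.0–4.0 at low
dispersion (0.40). These defaults guarantee the lesion load stays below
10 % of brain voxels even for worst-case draws, and make count, component
size and scatter — the discriminative features of the real diseases — the
classes' separating statistics. All randomness flows from explicit seeds
through `numpy` `SeedSequence` spawning; generation is bit-reproducible.

What the phantoms do **not** emulate: anatomy (no ventricles, cortex or
white/grey contrast), MR physics (no bias fields, partial-volume effects
or structured noise), inter-scanner variability, and ambiguous lesion
boundaries. Passing the desk-scale tests therefore demonstrates that the
architecture, losses and training loop are implemented correctly and can
exploit separable lesion statistics — not that the model reaches clinical
performance on real T2-FLAIR data.

## Numerical and engineering choices

* The network runs on a package-internal reverse-mode autodiff engine
  (`lesionjoint.nn`): float32 tensors, conv3d as an offset-loop of
  channel-mixing contractions (no im2col memory blow-up at 160³), fused
  normalization backward rules, cached einsum contraction paths. Every
  backward rule is verified against central finite differences in the
  test suite; float64 inputs are honored so loss-level gradient checks
  can run at 1e-4 relative tolerance.
* Resampling uses separable 1-D interpolation matrices (half-pixel-center
  convention) for both the differentiable ops and the preprocessing
  `resize_volume`; output shapes are exact and runs are deterministic.
* Z-score normalization uses the population SD over the full cropped grid
  (brain-only statistics optional); zero-variance volumes raise. Crop
  threshold default 0 (strict background). The pipeline resizes then
  normalizes (order configurable).
* Metric computations treat undefined quantities (empty ground-truth
  masks, single-class folds) as missing values, never as zeros; fold
  aggregation excludes them with a warning.
* VD is reported with absolute value, |#pred − #truth| / #truth, matching
  its use as a "lower is better" percentage. Accuracy uses the standard
  TP+TN over all cases.
* Min–max normalization inside the cross-task loss and CAM export is
  computed per tensor; its min/max are differentiated through the argmin/
  argmax voxel (exact almost everywhere).
* Checkpoints are single `.npz` files with the model configuration
  embedded as JSON; loading reconstructs the configuration and verifies
  every parameter shape.

## Known limitations

* Single modality, single channel; no multi-sequence input.
* No boundary masking in shifted-window attention (see above).
* The engine is CPU-only and single-threaded beyond BLAS; full-scale
  (160³) training is out of reach — full-scale code paths are exercised
  by forward-pass shape checks only.
* The phantom classes are far easier to separate than MS vs. NMOSD on
  clinical data; reported desk-scale metrics characterize the
  implementation, not clinical performance.
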