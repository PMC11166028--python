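# lesionjoint

Joint 3-D lesion segmentation and disease classification for MS vs. NMOSD
brain MRI.

Multiple sclerosis (MS) and neuromyelitis optica spectrum disorder (NMOSD)
are mimic demyelinating diseases: both present as hyperintense white-matter
lesions on T2-FLAIR, and telling them apart hinges on lesion morphology and
spatial distribution — exactly the information a lesion segmentation
produces. `lesionjoint` implements a multi-task network that performs both
tasks at once and lets each guide the other:

* **Information-sharing subnetwork** — a dual-branch encoder over the input
  volume `I`: a local branch (`CTX_local = Conv(LN(I))`, three 3×3×3
  convolutions, first stride 2) and a global branch
  (`CTX_global = UP(ST(LN(E)))`, `E = PE(I)` a patch embedding on a /16
  token grid followed by two shifted-window self-attention layers, window
  5³). A learnable 2×2 cross-stitch mixes the branches per task:
  `f_seg = w_seg,1·CTX_local + w_seg,2·CTX_global` and symmetrically for
  `f_cls`; both are emitted at half resolution (32 × 80³ for a 160³ input).
* **Segmentation subnetwork** — a U-shaped encoder–decoder over `f_seg`;
  single-channel maps from four decoder scales (L/8 … L) are upsampled and
  fused as `M_lesion = sigmoid(Σ_i α_i · Up(f_1×1(f_seg,i)))` with
  α = (0.25, 0.25, 0.5, 1).
* **Lesion Guidance Module (LGM)** — the lesion probability map gates the
  classification features (`D' = sigmoid(conv(P)) ⊙ D`) and its downsampled
  copy is concatenated back in, so the classifier attends to lesions rather
  than the bulk of normal tissue.
* **Classification subnetwork** — three residual stages (64/128/256
  channels), global average pooling after each stage, one fully connected
  layer and a softmax over {MS, NMOSD}.
* **Objectives** — `L = β₁·L_seg + β₂·L_cls + β₃·L_cross` with
  β = (1, 0.8, 1): soft Dice for segmentation, binary cross-entropy for
  classification, and a cross-task loss
  `L_cross = Σ_i η_i · ‖S_i − V_i‖²`, η = (0.25, 0.25, 0.5), that pulls the
  classifier's class-activation maps `V_i = Σ_k F_i,k · w^c_i,k` toward the
  intermediate segmentation maps `S_i`.

Everything runs on a self-contained numpy autodiff engine
(`lesionjoint.nn`) — no GPU framework required — and is fully
size-parameterized, so the full-scale (160³) and desk-scale (32³)
instantiations share one code path. A two-class lesion-phantom generator
(`lesionjoint.synthetic_data`) provides labeled volumes with exact
ground-truth masks: MS-like cases carry many small scattered lesions,
NMOSD-like cases few large compact ones.

## Worked example

```python
from lesionjoint import ModelConfig, PhantomParams
from lesionjoint.synthetic_data import generate_dataset
from lesionjoint.workflow import TrainConfig, make_folds, run_cross_validation

cases = generate_dataset(30, PhantomParams(grid_size=32), seed=20240527)
split = make_folds(cases, k=2, seed=20240527)
result = run_cross_validation(cases, split,
                              ModelConfig.desk(),
                              TrainConfig.desk(epochs=30, seed=20240527))
print(result["summary"].round(3).to_string())
```

prints (fractions; multiply by 100 for the usual percent tables)

```
        DSC    PPV    TPR     VD    ACC   SN     SP  AUC
mean  0.794  0.759  0.851  0.240  0.983  1.0  0.967  1.0
sd    0.045  0.035  0.045  0.066  0.017  0.0  0.033  0.0
```

Read: on held-out phantoms the joint model overlaps the true lesion masks
at Dice ≈ 0.79 with recall above precision and a ~24 % lesion-volume
overshoot, and separates the two phantom classes nearly perfectly
(ACC 0.98, AUC 1.0). Each fold's model never saw its evaluation cases;
the run takes ~8 minutes on one CPU core.

The same pipeline is scriptable from the shell:

```bash
lesionjoint simulate --n-per-class 30 --grid 32 --seed 1 --out data/
lesionjoint split --manifest data/manifest.csv --k 2 --seed 1 --out split.json
lesionjoint train --manifest data/manifest.csv --split-file split.json \
    --profile desk --epochs 30 --seed 1 --out runs/joint
lesionjoint ablate --manifest data/manifest.csv --split-file split.json \
    --profile desk --epochs 30 --seed 1 --out runs/ablations
lesionjoint explain --volume data/case_0000_vol.nii.gz \
    --checkpoint runs/joint/fold0_model.npz --out maps/
```

`ablate` reruns the identical cross-validation per configuration switch
(no sharing / local-only / global-only trunk, LGM variants, no cross-task
loss) on one shared split, producing a comparable table. `explain` writes
CAM and Grad-CAM lesion-localization heat volumes as NIfTI.

Real clinical volumes must arrive skull-stripped and bias-corrected
(standard BET/N4 tooling); `lesionjoint preprocess` then applies background
cropping, resampling to the working grid and Z-score normalization.

## Layout

```
src/lesionjoint/
  nn/              autodiff engine: tensor ops, layers, Adam
  synthetic_data   two-class lesion phantoms + augmentation
  preprocess       crop / resize / Z-score, NIfTI I/O
  joint_model      the network (shared trunk, seg head, LGM, cls head)
  objectives       Dice, BCE, CAM maps, cross-task loss, total loss
  metrics          DSC/PPV/TPR/VD, ACC/SN/SP/AUC, fold aggregation
  workflow         training loop, k-fold CV, ablations, explanation
  cli              `lesionjoint` command group
```

See `docs/methods.md` for modeling assumptions and numerical choices.
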