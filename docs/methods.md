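# Methods

## Model

`dsaseg` segments focal cortical dysplasia (FCD) lesions from 3D
multi-channel MR patches with an encoder–decoder convolutional network
whose skip connections at scales 1/4–1/32 pass through transformer
pathways of dual-self-attention (DSA) modules. The design assumptions
are:

* inputs are co-registered, skull-stripped volumes (zero outside the
  brain) with lesions annotated as binary masks; the package performs
  only intensity normalisation, not registration or skull stripping;
* patches have spatial extents divisible by 32 (the encoder halves five
  times); the full volume is handled by sliding-window inference;
* lesions are sparse foreground — the loss and the patch sampler are
  chosen for extreme class imbalance.

### Encoder

Six levels of residual convolution modules (`ResConv`): two
conv(3×3×3)–norm–activation blocks plus a shortcut, added after the
second activation, so a zero-weight module reduces exactly to its
shortcut. Level 1 keeps full resolution; levels 2–6 downsample with a
stride-2 convolution in their first block (kept learnable rather than
using pooling). The shortcut is the identity where shapes permit,
otherwise a 1×1×1 convolution with matching stride. Level *i* carries
`2^(i-1)·C` channels.

Normalisation is instance normalisation and the activation a leaky
rectifier (slope 0.01) — standard choices for small-batch 3D
segmentation; both are config-switchable (`norm_kind`, `act_kind`).
Weights are fan-in-scaled Gaussian, drawn from a generator seeded by
the single run seed.

### Transformer pathways

Each pathway first halves its level's channels with a `ResConv`, then
applies `m = 3` DSA modules (configurable), each with its own
parameters and zero-initialised positional embedding `e ∈ R^{n×c}`.
Inside a DSA module the tokens are embedded, layer-normalised, and
passed to two branches sharing `Q` and `K`:

* SSA: `K̄ = E_k K`, `V̄_s = E_v V_s` with learnable `E ∈ R^{p×n}`;
  `A_s = softmax(Q K̄ᵀ/√s)`, `x_s = A_s V̄_s`;
* CSA: `A_c = softmax(Qᵀ K/√s)` (normalised along its last axis,
  mirroring `A_s` — a convention, since either axis is defensible),
  `x_c = V_c A_c`;

with `s = c/n_h`. Heads partition the channel axis and their outputs
are concatenated; there is no extra output projection. The fused
residual is taken over the layer-normalised tokens,
`z' = x + (x_s + x_c)`, i.e. the residual wraps everything after the
LayerNorm; the alternative (pre-norm residual) differs only by where
the normalisation sits and was not used because the module is specified
as tokenise → normalise → attend → residual. The convolutional tail is
`z' + Conv1×1×1(ResConv(z'))` — the 1×1×1 convolution and the residual
wrap the `ResConv` together, resolving an ambiguity in favour of one
residual around the whole tail.

Defaults `p = 64` and `n_h = 8` are package choices (`p` is clamped to
`n` on pathways whose sequence is shorter, e.g. the deepest level of a
small patch): `p = 64` keeps `p ≪ n` at every pathway of a 128³ patch
(n = 32768…64), and `n_h = 8` divides every pathway channel count for
the full-width configuration (32–256 channels). A single attention
dropout rate is exposed (default 0, keeping runs deterministic).

### Decoder and head

Walking from level 6 to 1: a 2×2×2 transposed convolution (stride 2)
doubles resolution and halves channels, the skip is concatenated —
pathway output `z_i` at levels 3–6, raw encoder feature `x_i` at levels
1–2 where no pathway exists — and one `ResConv` fuses (switchable to a
plain double convolution). Pathway outputs are computed once per
forward pass. A 1×1×1 convolution to two channels and a channel softmax
produce the probability map; no deep supervision. Because positional
embeddings and token projections are sized by `n`, a model is bound to
its patch geometry at build time and stored (with config, optimiser
moments, step and RNG state) in a versioned `.npz` checkpoint.

## Objective

`L = L_dice + ω·L_ce` on the foreground softmax channel, `ω = 1`.
`L_dice = 1 − (2ΣPG + ε)/(ΣP + ΣG + ε)` with `ε = 1e-5` (config-
exposed). Cross-entropy is the binary form on the foreground
probability, clipped to `[1e-7, 1−1e-7]`, and **averaged over voxels**
so that `ω = 1` means the same thing at every patch size; this is a
documented convention, as is computing the loss per patch and averaging
over the batch. Dice uses the foreground channel only, since the
objective is written over a single probability map `P`.

## Evaluation

* A subject counts as detected when prediction and ground truth share
  at least one voxel; `sSens = TPs/(TPs+FNs)` over **lesional**
  subjects. Subjects with empty ground truth cannot be a TP or FN and
  are excluded from the `sSens` denominator; they still contribute
  false-positive clusters to `nFPC`.
* Clusters are maximal connected components, default 26-connectivity
  (standard for 3D lesion counting; 6 and 18 available). A predicted
  cluster with no ground-truth voxel is a false-positive cluster; a
  minimum-cluster-size filter exists but is off by default.
* Voxel metrics `Prec`, `Sens`, `DC` are per-subject ratios; a ratio
  with zero denominator is recorded as missing (not zero) and skipped
  in cohort means. Cohort spreads are population (ddof = 0) standard
  deviations, which reproduces the reference spread for counts such as
  three singleton FP clusters among 17 subjects (0.176 ± 0.381).
* Probability maps are binarised by `P_fg ≥ 0.5` (equivalently channel
  argmax), threshold config-exposed.

## Phantoms

`generate_phantom` emulates the statistical structure of the target
data, not its anatomy: a spherical brain support (zero outside, as in
skull-stripped images) holding concentric smooth intensity bands plus a
smooth random bias field; at most one lesion per subject — a blurred
ellipsoid (radii 3–7 voxels, edge blur σ = 1) that adds +1.5 SD to the
FLAIR-like channel and +0.4 SD to the T1-like channel; Gaussian voxel
noise (σ = 0.1); per-channel z-scoring over the support at write time,
making the preprocessing step a near-no-op on phantoms. The mask is the
pre-blur ellipsoid. `generate_cohort` writes NIfTI triplets plus a
manifest, assigns train/val/test at proportions mirroring a 62/6/17
split of 85, and leaves a configurable fraction (default 7/85) of
subjects lesion-free to emulate MRI-negative cases.

Because the lesion is a bright blob on an otherwise smooth background,
a thin network learns it quickly; passing the phantom learnability test
shows the optimisation and inference machinery work end to end, and
says nothing about performance on real FCD, where lesions are subtle,
textured and confounded by normal cortex.

## Runtime and numerics

* The network runs on an in-package reverse-mode autodiff engine over
  NumPy with im2col-based 3D convolution (columns gathered one kernel
  offset at a time, which is markedly faster than a strided-view copy)
  and an einsum-based 2×2×2 transposed convolution. All gradients are
  verified against central finite differences in the test suite.
* Optimiser: Adam (β = 0.9/0.999, ε = 1e-8) with cosine decay and
  global-norm gradient clipping at 1.0. The full-scale default learning
  rate is 1e-4; the desk-scale preset (`RunConfig.desk_scale`) uses
  1e-3, appropriate for few-hundred-step from-scratch runs.
* Patch sampling: 50 % of patches centred (with jitter) on a random
  lesion voxel, 50 % uniform, countering foreground sparsity.
* Sliding-window inference: 0.5 overlap, Gaussian importance blending
  (σ = patch/8, floored at 1e-3 of the peak); symmetric zero-padding
  when a volume is smaller than the patch; blending preserves per-voxel
  channel sums exactly.
* One root seed drives weight init, patch sampling and cohort
  generation; checkpoints store the sampler's RNG state, so a resumed
  run reproduces the uninterrupted one bit-for-bit (verified to 1e-6 in
  tests). Resuming takes the caller's config, so schedules can be
  extended.
* Degenerate geometry: at 32³ patches the deepest level is 1×1×1, where
  instance normalisation flattens its input to the bias — the level-6
  convolution weights then receive no gradient. This is harmless for
  desk-scale smoke runs and absent at 64³ and larger patches (the
  no-dead-branch property is tested at 64³).

## Problem sizes used in tests

Unit and acceptance tests run thin-width models (2–4 first-level
filters, 1–2 heads, 8–16-token projections) on 32³–64³ patches, and the
learnability check trains 200 steps on four 32³ phantoms — sizes chosen
so the whole suite runs on one CPU in minutes while exercising every
code path of the full-width model, which differs only in configuration
values.

## Known limitations

* No windowed attention, relative position bias, deep supervision, or
  surface-distance metrics (HD95/ASSD); comparison baselines are not
  reimplemented.
* A model checkpoint is tied to its patch size; predicting at a
  different patch size requires rebuilding and retraining.
* Phantoms are non-anatomical (no cortical ribbon geometry, no MR
  physics); DICOM ingestion and registration/skull-stripping are out of
  scope.
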