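# Methods

This note records the model as implemented, the conventions chosen where
reporting practice varies, and what the synthetic-data experiments do and
do not establish.

## Architecture

The network is a two-phase encoder–decoder ("Double U-Net") for 3-class
segmentation (background / cytoplasm / nucleus) of RGB microscopy images
whose sides are divisible by 8.

**Phase 1.** Four VGG-19-style encoder blocks (2, 2, 4, 4 convolutions of
width 64, 128, 256, 512 by default), with 2×2 max pooling after blocks
1–3. Block 4's output therefore sits at 1/8 resolution — 28×28×512 for a
224×224 input, 64×64×512 at 512×512 — and feeds the bottleneck cascade:
attention-augmented convolution (AAC), gating, then atrous spatial pyramid
pooling (ASPP). Each of the three bottleneck stages can be toggled off for
ablations (AAC and gating via `use_aac` / `use_gating`; ASPP is always
present, as in the base architecture).

**Conditional upsampling.** Three pooling stages admit exactly three ×2
upsamplings back to full resolution, yet each phase carries four decoder
blocks whose outputs are needed as Phase-2 skips at four resolutions. The
decoders therefore mirror the Phase-2 encoder's conditional pooling: the
deepest decoder block fuses the stage-4 skip at 1/8 resolution *without*
upsampling, and the remaining three blocks upsample bilinearly ×2 before
fusing the matching shallower skip. Every decoder block is
[concat → two Conv-BN-ReLU → squeeze-and-excitation (SE)]. This is the only
arrangement consistent with both the stated bottleneck resolution and a
four-deep decoder, and it gives Phase 2's decoder a Phase-1 partner at
every stage (1/8, 1/4, 1/2, 1/1).

**Phase 2.** Input is the image multiplied by Phase 1's foreground
probability (1 − background probability), broadcast over color channels.
During training a `teacher_forcing` flag can substitute the ground-truth
foreground (the formulation the refinement stage is defined with); the
default uses the prediction so that inference is self-contained. The
Phase-2 encoder has four blocks of two Conv-BN-ReLU layers, each ending in
SE, with conditional pooling (block 1 unpooled, blocks 2–4 pooled); its
bottleneck repeats the (AAC → gating → ASPP) cascade with its own
parameters. Each Phase-2 decoder block concatenates upsampled features,
the Phase-2 encoder skip, and the Phase-1 decoder output of the same
resolution. The two phase probability maps (3 channels each) are
concatenated and fused by a learnable 1×1 convolution + softmax; all three
maps are returned for deep supervision.

## Attention-augmented convolution

`AAConv2d` concatenates, along channels, a k×k convolution producing
`out_channels − dv_total` channels with a multi-head self-attention branch
producing `dv_total` channels, followed (by default) by BatchNorm + ReLU
on the concatenated output. Conventions:

* "32-dimensional keys and values across four heads" is read as *totals*:
  `dk_total = dv_total = 32`, i.e. 8 per head. Both totals are plain config
  fields, so the per-head reading is a one-line change.
* Attention logits are `(q/√dk_head)·kᵀ` plus relative-position terms
  `(q/√dk_head)·(r_row[Δrow] + r_col[Δcol])`: the query is scaled once and
  used for both content and relative logits (the canonical 2-D
  relative-attention construction). The embedding tables have `2H−1` and
  `2W−1` rows (sized from `input_size/8` at construction), per-head key
  dimension, shared across heads. Equal displacements address equal table
  rows, making the term translation-consistent.
* The attention branch ends in a bias-free 1×1 output projection on its
  `dv_total` channels; the convolution branch uses kernel 3 with same
  padding. Softmax is computed with max-subtraction for stability; per
  query and head the weights over all H·W keys sum to 1.
* Only stride 1 is exercised (no other stride is specified anywhere).

## Gating, SE, ASPP

* Gating: `z = x ⊙ σ(Conv₂(ReLU(BN(Conv₁(x)))))` with 1×1 convolutions
  C → ⌊C/2⌋ → C (floor, minimum 1, so odd widths don't crash). The sigmoid
  bounds every gate in (0, 1), giving |z| ≤ |x| elementwise with sign
  preserved.
* SE: global average pool → C → ⌈C/r⌉ → C bottleneck with ReLU then
  sigmoid; reduction r = 8 by default. The bottleneck bias is initialized
  to 0.1 to keep excitation units off the dead-ReLU boundary at init
  (inputs are nonnegative pooled activations).
* ASPP: 1×1 branch, one 3×3 dilated branch per rate (default 6, 12, 18 —
  the rates of the base architecture this extends), and a global-pooling
  branch, concatenated and projected by 1×1 convolution to `aspp_out`
  (default 256).
* Convolutions immediately followed by BatchNorm are bias-free: the
  normalization's mean subtraction would cancel the bias exactly, leaving
  a permanently zero-gradient parameter.
* BatchNorm is used after every convolution (including the VGG-style
  encoder) because the encoder trains from random initialization here; no
  pretrained weights are downloaded or bundled.

## Loss and training

Multi-class soft Dice per output map: for class c,
`dice_c = (2Σp_c g_c + ε)/(Σp_c + Σg_c + ε)` with ε = 1e-6 and one-hot g;
loss = 1 − mean over classes (unweighted, background included), averaged
over the batch. With Σg_c = 0 and vanishing prediction mass the smoothed
ratio tends to 1 — absent classes are not penalized. The training loss
sums the Phase-1, Phase-2 and fused-map losses with weights (1, 1, 1)
(configurable).

Defaults follow the recipe the model was designed with: Adam at 1e-4,
polynomial learning-rate decay `lr·(1 − step/total)^0.9` over the full
step budget (power unstated upstream; 0.9 is the common choice), batch
size 16 at 224×224 or 4 at 512×512, and the augmentation policy below.
All randomness (init, shuffling, augmentation) flows from one seed; the
run log records per-epoch loss, learning-rate trace, and train/validation
accuracy, macro DSC and macro IoU (`metrics_every` thins the metric
evaluations for small fast runs). The best-validation-DSC parameters are
checkpointed to a single `.npz` with a config echo and format version.

## Metrics conventions

* Overlap metrics are one-vs-rest from pixel confusion counts; "mean"
  IoU/DSC are unweighted macro averages over all three classes, with an
  `include_background=False` / `--exclude-background` switch.
* Surface points are class pixels with ≥1 of their 4-neighbors outside the
  class; the image border counts as outside. Distances are Euclidean in
  pixel units on pixel centers (no physical spacing is assumed). HD95 uses
  linear interpolation for the 95th percentile; HD95/ASSD are computed for
  the two foreground classes and macro-averaged.
* Empty-class policy: absent from both masks → skipped from the macro
  mean; absent from exactly one → IoU = DSC = 0 and surface distances set
  to the image diagonal, with the class flagged in the report.
* Argmax ties break to the lowest class index (deterministic predictions).

## Synthetic scenes

`generate_scene` renders elliptical cells — a cytoplasm ellipse (label 1)
strictly enclosing one nucleus ellipse (label 2, radius a configurable
fraction of the cytoplasm's with a 1.5 px margin) — over a textured pale
background with red-blood-cell-like distractor rings that carry no label,
emulating the challenges of real smear sets: variable cell density,
stain/brightness variation, background clutter, and (with
`allow_overlap`) adhesion. Additive Gaussian noise (σ up to 0.03 of
dynamic range) and a global brightness shift (±0.1) complete the scene.
Identical spec + seed reproduces scenes bit-for-bit. Default geometry
(radius 20–45 px, 1–4 cells) is stated for a 224 px canvas and scaled
proportionally for other sizes (e.g. 9–19 px at 96 px).

What it does *not* emulate: real stain chemistry, the five WBC subtype
morphologies, lobed nuclei, focus/illumination gradients, or annotation
noise. Passing tests on these scenes demonstrates that the architecture,
optimization and metrics are wired correctly and can fit cell-like
structure — not that the model reaches any particular accuracy on real
benchmark data.

## Augmentation

Horizontal flip, vertical flip, rotation, Gaussian noise and brightness
shift, each firing independently with probability 0.5. Rotation defaults
to {90°, 180°, 270°} so masks need no interpolation (exact invertibility);
a free-angle mode warps the mask with nearest-neighbor resampling. Noise
σ = 0.02 and brightness ±15% by default (magnitudes are unspecified
upstream; these are conservative). Geometric ops transform image and mask
identically; photometric ops touch only the image.

## Numerical engine

A minimal reverse-mode autodiff on NumPy float32: conv2d as im2col + BLAS
GEMM (pointwise fast path for 1×1), fused BatchNorm forward/backward,
bilinear resampling as cached interpolation-matrix products, stable
softmax. Every gradient rule is checked against central finite differences,
and the full model passes an end-to-end finite-difference spot check.
Evaluation mode uses running BatchNorm statistics, making forward passes
deterministic affine maps — algebraic identity tests run in that mode.

## Scaled-down experiment sizes

CPU-scale runs use deliberately small problems: the learning-capacity
check trains the width-÷4 model (encoder 16–128 channels) on eight 96×96
scenes for 200 steps at Adam 1e-2 — the base 1e-4 rate is tuned for long
schedules on real data and barely moves a tiny model in 200 steps, so the
demo uses the standard small-model rate — reaching training DSC > 0.99.
The CLI smoke chain runs six 64×64 scenes for 2 epochs. Architecture
contracts are exercised at full width (36.2 M parameters) for single
forward passes at 224×224 and 512×512.

## Known limitations

* CPU-only; a 512×512 full-width forward pass takes tens of seconds, so
  full-scale training on real benchmarks is impractical here — benchmark
  accuracy reproduction is out of scope.
* No pretrained VGG-19 weights: encoder 1 is randomly initialized, which
  changes the low-data behavior relative to a pretrained encoder.
* The Phase-2 input gate uses predicted foreground at inference by
  necessity; with teacher forcing enabled, train/inference inputs differ
  (classic exposure bias) — both modes are exposed.
* Surface metrics are defined on pixel centers without spacing metadata;
  values are not comparable across images resized to different scales.
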