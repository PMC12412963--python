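# Methods

This note records the model, the conventions behind the complexity
accounting, the synthetic-scene generator, the training regime, and the
design decisions taken where the architecture's published description is
ambiguous.

## The detector

`yolocf` is an anchor-based one-stage detector in the YOLOv5 lineage.  An
input image (3×S×S, S divisible by 32) passes through a backbone that
produces features at strides 8, 16 and 32; a path-aggregation neck (PAFPN)
fuses the three scales top-down and bottom-up; a *coupled head* — a single
1×1 convolution per scale — emits, for each of 3 anchors per cell,
`(t_x, t_y, t_w, t_h, t_obj, t_c1 … t_cnc)`.  Predictions are decoded
against per-scale anchor priors:

    xy = (2σ(t_xy) − 0.5 + grid) · stride        wh = (2σ(t_wh))² · anchor

so a cell can place a center slightly outside itself and box dimensions are
bounded by 4× the anchor.  Score = σ(t_obj)·max_c σ(t_c).

### Blocks

All convolutions are CBS units (conv → batch norm → SiLU; no conv bias —
the BN affine term supplies it).

* **MPC** (downsampling): two branches, each opened by a 1×1 CBS at the
  incoming resolution and carrying half the output channels; one branch
  max-pools 2×2/s2, the other applies a 3×3 stride-2 CBS; outputs are
  concatenated.  The pooled branch preserves strong local activations that
  a strided convolution would smooth away; the conv branch stays learnable.
* **C4**: the bottleneck replacement.  A 1×1 CBS expands `c → 2c`; the
  result is split channel-wise into two halves; each half runs its own 3×3
  CBS (`c → c`); the concatenation (2c) is projected back to `c` by a final
  1×1 CBS.  Exactly four CBS units; no residual addition — the text of the
  original description mentions only concatenation.
* **C2fR**: a cross-stage partial block with C4 inside.  Two parallel 1×1
  CBS entries at half the output width; one stream passes through `n`
  chained C4 units; the streams are concatenated and fused by a final 1×1
  CBS.  This is the three-CBS wrapper ("two CBS with C4 in the middle …
  final CBS"); the alternative C2f-style wrapper that additionally retains
  every intermediate C4 output remains available (``C2fR(..., retain=True)``)
  but lost the complexity calibration (below) and is not used in the
  shipped variants.
* **SPPR**: reduced spatial pyramid pooling — one 5×5 stride-1 max pool
  (kernel fixed at SPPF's 5; no kernel is published), concatenated with its
  input at half width, then projected.  Against SPPF this removes two
  chained pools and shrinks the fuse convolution's input from 4·c to 2·c.
* **C3 / C2f / SPPF** are faithful ports of the public YOLOv5/YOLOv8 blocks
  and exist for the ablation variants and reference comparisons.

### Assembly and scaling

Backbone layer table (channels after width-scaling 0.25 of the
64→1024 ladder, i.e. 16/32/64/128/256):

    L0 stem: CBS 3→16 3×3/s2, then CBS 16→16 3×3/s1
    L1 CBS 16→32 3×3/s2
    L2 C-slot 32      L3 MPC 32→64
    L4 C-slot 64      L5 MPC 64→128
    L6 C-slot 128     L7 MPC 128→256
    L8 C-slot 256     L9 SPPR 256

Neck: upsample–concat–C2fR twice (384→128 at stride 16, 192→64 at stride
8), then stride-2 CBS–concat–C2fR twice (192→128, 384→256), C2fR
everywhere and in every variant.  Depth scaling 0.33 acts on a uniform
per-slot base of 3, giving one structural unit per C-slot and per neck
block (`max(round(3·0.33), 1) = 1`).

The five ablation variants fill the four backbone C-slots with C2f (cf1),
C3/C2f alternating (cf2), C3/C2fR alternating (cf3), C3 (cf4) or C2fR
(cf5 — the full detector).

### Calibration of the ambiguous topology choices

The published description of MPC, C4, C2fR and the stem under-determines
the architecture; the printed per-variant parameter/GFLOPs table is the
only quantitative anchor, so the open choices were fixed by matching it.
The chosen configuration reproduces, at one decimal: cf5 = 2.1 M / 5.2
GFLOPs, cf3 = 2.0 M, cf1 = 5.1 GFLOPs, and the full printed GFLOPs
ordering cf4 < cf2 ≤ cf3 < cf1 < cf5 holds before rounding.  Two printed
GFLOPs rows are *not* reproduced (cf2: 4.9 here vs. 5.0; cf4: 4.6 vs. 4.9)
and provably cannot be while the others hold: the cost difference between
faithful public C2f and C3 slots is ≈ 0.26 GFLOPs per slot pair at this
scale, larger than the 0.1-step spacing of the printed rows, and within
one C-slot every convolution runs at a single resolution, so parameter and
FLOP orderings cannot diverge the way the printed table requires.  The
residual is an irreducible property of that table, not a tunable of this
implementation.

## Complexity accounting

* Parameters: every trainable scalar — convolution kernels, head biases,
  and batch-norm affine pairs (2 per channel).  `count_params` enumerates
  the arrays; `count_params_analytic` re-derives the total from layer
  hyper-parameters (`i·k²·o (+o)` per conv, `2c` per BN); the test suite
  pins them equal, and an arithmetic oracle in the tests checks both.
* FLOPs, `mac2_standard` (the headline convention): `2·H·W·i·k²·o` per
  convolution at its output resolution, bias adds `H·W·o`; pooling,
  activations, concatenation and upsampling are ignored, as detector
  papers conventionally do.  Profiling is trace-based: a forward pass
  records every leaf layer with its observed output shape, so the counter
  can never drift from the executed graph.
* FLOPs, `eq7_paper`: the layer-wise "output area × layer parameters"
  formula (one op per MAC, BN included).  Kept because the source
  describes this form; not used for headline numbers.

For a fully convolutional network both conventions scale exactly with
H·W, which the tests assert.

## Losses and target assignment

Box regression uses the complete-IoU loss
`1 − IoU + ρ²/c² + α·v` with `v = (4/π²)(arctan(w_g/h_g) − arctan(w/h))²`
and `α = v/((1−IoU)+v)` treated as constant under differentiation.
Objectness and classification use binary cross-entropy on logits.
Assignment follows the anchor-ratio rule: a ground-truth box matches every
anchor with per-dimension ratio in (1/4, 4) in its own cell and the two
nearest neighbour cells (0.5-cell offset).  Loss weights are the platform
defaults — box 0.05, objectness 1.0 with per-scale balance (4.0, 1.0,
0.4), class 0.5 — since the source states only "other default
parameters".  Objectness targets at assigned cells are the detached
prediction IoU (clipped at 0).  ε = 1e-7 guards IoU denominators and
logarithms.

## Runtime stack

No deep-learning framework is used: the package carries a small
reverse-mode automatic-differentiation engine on NumPy (float32), with
convolution as im2col + BLAS matmul, kernel-offset loops for the
col2im adjoint, argmax-tracked max-pooling, nearest upsampling and a fused
batch-norm op (momentum 0.03, eps 1e-3 on running statistics).  Every
operator's backward is validated against central finite differences, and
the fused batch-norm against the same normalization composed from
primitive ops.  Training uses SGD with momentum and weight decay applied
only to convolution kernels, under a linear-warmup + cosine schedule.

## Synthetic scenes

The generator emulates the difficulty factors of field fruit images:
seven visually distinct fruit classes (colour family, round/elongated
shape, texture amplitude, size range), fruit clusters, overlap, leaf and
branch occluders drawn over fruits, dense target counts, four illumination
regimes (high light, low light, backlight, side light) and three
background families (earth, fruit-coloured foliage, sky).  A
``size_scale`` knob switches between distant-canopy framing (1.0, the
mixed-conditions default) and close-range framing (2.0, the easy
preset).  Boxes annotate
the full amodal fruit extent — standard orchard-annotation practice — and
an occluder is only committed if every affected fruit keeps at least 25%
of its pixels visible, so no target is unlearnable.  Labels are exact
analytic ellipse extents, clipped to the image.  One integer seed drives a
hierarchical stream (dataset → scene → object), making any subset
bit-reproducible.

What the generator does *not* emulate: photorealistic appearance, natural
texture statistics, camera noise structure, perspective foreshortening, or
inter-class co-occurrence.  A detector that works here has demonstrated
that assignment, losses, optimisation, decoding and evaluation compose
correctly — not that it would reach any particular accuracy on real
orchard images.

## Training regimes

Defaults mirror the published regime: 640 px, batch 16, 200 epochs,
momentum 0.937, HSV gains 0.015/0.7/0.4, translate 0.1, scale 0.5, mosaic
1.0; learning rate (0.01, cosine to 1%, 3-epoch warmup) and flip 0.5 are
platform defaults, unstated in the source.  Anchors are re-estimated from
the training labels by IoU-distance k-means with a best-possible-recall
fallback to the default table.

The test suite exercises a scaled-down smoke regime chosen once from
pilot runs: the `easy` preset (sparse, unoccluded, bright, close-range
framing), 200 train / 50 val images at 160 px, 30 epochs, batch 8, lr
0.05 with a 2-epoch warmup, mosaic probability 0.5 and affine scale
jitter 0.2.  Close-range framing matters: at distant-canopy framing the
fruits are 4–27 px at this resolution and the run becomes a small-object
problem that needs far more steps than a smoke test allows; with 2×
framing the network reaches mAP@0.5 ≈ 0.65–0.70 in ~750 optimisation
steps, minutes on one CPU.

## Numerical and degenerate-case choices

* Even-kernel convolutions pad `(k−1)//2`; all kernels in the shipped
  architecture are odd.
* NMS is class-aware, greedy, with deterministic tie-breaking (score,
  then box area, then input order); IoU threshold 0.45; confidence 0.25
  for inference and 0.001 when sweeping PR curves.
* AP integrates the interpolated precision envelope at 101 evenly spaced
  recall points; classes without ground truth are excluded from the mAP
  mean.  With no detections, precision is reported as 0.
* `count_analysis` refuses constant true-count vectors (R² undefined) and
  vectors shorter than 2.
* Per-image counts pool all classes by default; a per-class mode exists
  because the published counting protocol does not say which was used.
* Letterboxing pads with grey 114 and uses nearest resampling, keeping the
  geometry exactly invertible.

## Known limitations

* Pure-NumPy execution is single-threaded BLAS-bound: roughly 1–2 s per
  640-px image forward; training beyond the smoke scale is impractical.
* The train-mode batch-norm statistics make per-sample results depend on
  batch composition, as in any BN network.
* The two unreproducible GFLOPs table rows discussed above.
* Mosaic uses axis-aligned quadrant affine maps (no rotation/shear), and
  the affine augmentation is isotropic scale + translation only.
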