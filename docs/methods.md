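# Methods

## Problem and model

The package segments thin, branching crack structures (tongue
fissures) in close-up RGB photographs: a two-class per-pixel
classification in which the positive class occupies a few percent of
the image and is defined mostly by local contrast and elongated
geometry. The architecture is an encoder–decoder ("improved U-Net"):

1. **Encoder.** Four stages of one of four block families
   (`googlenet` Inception blocks, `vgg` conv pairs, `seresnet`
   residual + squeeze-excitation blocks, `plain_unet` double-conv
   blocks). The three backbone families share a stride-4 stem (two
   3×3/stride-2 conv-BN-relu layers) and pool between stages, giving
   features at strides 4/8/16/32; the plain path keeps the classic
   U-Net layout (stem at stride 1, stages at 2/4/8/16). Stage widths
   are 2·b, 4·b, 8·b, 16·b for `base_channels = b`, so one parameter
   scales the model from desk size (b=8–16) to clinical size (b=32+).
   Inception branch widths split an out-width C as C/4 (1×1), C/2
   (3×3), C/8 (5×5), C/8 (pool-proj), with reduce widths of half the
   branch width; this forces `base_channels` to be a multiple of 8.
2. **GCN skip blocks.** Each stage output is mapped to
   `num_classes` channels by a Global Convolutional Network block: the
   sum of a (k×1 → 1×k) and a (1×k → k×1) branch, bias-free and with
   no normalization or nonlinearity, so the block is exactly linear
   with a k×k receptive field but parameter cost linear in k. The
   `separable` variant (GCN_D) replaces each constituent convolution
   with depthwise-then-pointwise factors. Default k=7: large enough to
   couple a crack's neighborhood into the per-pixel classifier at
   stride 4, small enough that the desk model stays under 50k
   parameters.
3. **Boundary Refinement.** `x + conv3x3(relu(conv3x3(x)))` with the
   second convolution zero-initialized: the block starts as the exact
   identity and learns a residual boundary correction. BR follows each
   GCN block and each decoder fusion.
4. **Decoder.** From the deepest score map: upsample ×2, add the next
   shallower GCN(+BR) output elementwise, apply BR; after the
   shallowest stage, repeat upsample(+BR) until full resolution.
   Score-map fusion is *addition* (the concat alternative is exposed
   via `fusion="concat"`, which inserts a 1×1 merge convolution).
   Upsampling is a learnable 2×2/stride-2 transposed convolution by
   default; a fixed bilinear kernel is available (`upsample=
   "bilinear"`). With `use_gcn=False` the same encoder drives a
   concatenation-skip U-Net with double-conv decoder blocks — the
   ablation baseline; `plain_unet` without GCN/BR is the textbook
   U-Net, and the suite checks its parameter count against an
   independent enumeration.

Prediction is per-pixel argmax with ties resolved toward background.

## Training

Pixel-wise cross-entropy, optionally class-weighted (weighted mean
normalized by the total weight, so uniform weights reduce to the plain
mean). Optimizer: Adam, first moment 0.9, second 0.999; the learning
rate decays per epoch as lr·decay^epoch (default decay 0.98, a concrete
form of "gradually decreasing"). Images are resized bilinearly to
`input_size`, scaled to [0,1], standardized with fixed constants
(mean 0.5, sd 0.25 per channel); masks are resized nearest-neighbor.
The loop retains the weights of the best validation-MIoU epoch.

Two named profiles:

* **clinical defaults** (`TrainConfig()`): 256×256, lr 1e-5, batch 4 —
  the regime appropriate when the encoder starts from pretrained
  weights and the dataset is real photographs.
* **desk profile** (`desk_train_config()` / `desk_model_config()`):
  64×64, lr 1e-3, batch 4, 20 epochs, `base_channels=16`, crack class
  upweighted 8× — the from-scratch CPU regime used by the tests and
  the acceptance script. The upweighting counters the ~6% positive
  fraction of the synthetic benchmark; without it the optimum over 20
  epochs is close to the all-background predictor. lr 1e-3 (not 1e-5)
  because training starts from random weights.

All randomness is seeded. A pipeline run fans one global seed out to
per-stage seeds by CRC-32 hashing of `"{seed}:{stage}"`, so stages are
independently reproducible; two identical runs produce byte-identical
metrics and history artifacts (asserted in the suite).

## Synthetic benchmark

`SyntheticParams` defines the generative model: a textured convex
ellipse (the tongue body, semi-axes 0.86/0.88 of the half-canvas) on a
dark backdrop; tissue texture is low-frequency Gaussian-smoothed noise
plus fine grain around a flesh-tone base color. Cracks are
bounded-turning random walks (step 3 px, turn ≤ 0.5 rad, ≤ 50 steps)
started inside the inner 70% of the ellipse, branching with
probability 0.06 per step (total polylines capped at 3× the primary
count of 3–6), rasterized and dilated to widths 1–3 px, darkened by
−70 intensity units with per-pixel jitter. The mask is exactly the
dilated skeleton ∩ ellipse. At the default 128×128 geometry the crack
fraction stays within [0.002, 0.15] over seeds (asserted for 50).

What it emulates: thin, branching, darker structures at a realistic
area fraction, inside a convex textured foreground, with pixel-exact
labels. What it does not: specular highlights, tongue coating color
classes, annotation noise, perspective, non-elliptical tongue shapes.
Passing tests therefore demonstrate that the architecture and pipeline
learn thin dark structures under controlled conditions — not clinical
performance, which depends on private data.

Per-sample seeds derive from `SeedSequence([seed, index])`, so subsets
of a dataset are reproducible independently of generation order.

## Metrics

Confusion matrix with rows = truth, columns = prediction; PA =
trace/total; IoU_c = TP/(TP+FP+FN); MIoU = mean over classes whose
union is nonzero (an absent class does not inflate the mean; an
entirely empty evaluation is an error). Dataset scores accumulate one
matrix over all images — per-image averaging is exposed as an option
but is not the default, since the two differ in general. MIoU ≤ PA is
*not* an invariant and is not asserted anywhere.

## Numerical choices and degenerate inputs

* The CNN kernel (`fissureseg._nn`) is float32 in training; all
  operations preserve input dtype, and the gradient checks run in
  float64 against central differences (tolerance 1e-5 relative).
* Convolutions evaluate as a loop over kernel taps (each a BLAS
  `tensordot`), avoiding im2col buffers; transposed 2×2/stride-2
  convolutions fill disjoint interleaved sub-grids.
* Batch normalization: momentum 0.1, eps 1e-5, unbiased running
  variance; evaluation mode uses running statistics.
* Max pooling breaks ties toward the first window position; argmax
  prediction breaks ties toward class 0.
* Polygon rasterization uses the even-odd crossing rule at pixel
  centers (x+0.5, y+0.5), half-open on edges, union over polygons. A
  pixel center exactly on an edge is resolved deterministically by the
  strict inequality of the crossing test.
* `split_dataset` uses `round(n · fraction)`; the 7:3 ratio at n=10
  gives exactly 7/3.
* Weight init is He-normal (fan-in) except the BR second convolution
  (zeros); model builds are deterministic given a seed.
* Degenerate inputs: empty id lists split to empty lists; zero crack
  count yields empty skeletons and all-zero masks; empty training sets,
  oversized crops, even GCN kernels, non-divisible input sizes, and
  unknown configuration keys raise named errors before any compute.

## Known limitations

* The GCN-path decoder carries only `num_classes` channels, so spatial
  detail finer than the shallowest skip stride must be reconstructed by
  the learned upsampling and BR blocks; at 64×64 with stride-4 skips
  this bounds achievable crack IoU well below 1 even with perfect
  classification (held-out fissure IoU ≈ 0.36 at the desk scale).
* Ablation tables on the synthetic benchmark report directional
  differences between encoder/GCN variants but the suite does not
  assert them: at desk scale, seed variance can exceed the gaps.
* The numpy kernel is single-threaded BLAS-bound and intended for
  small models; it is not a general deep-learning framework.
* Loading pretrained encoder weights is possible through
  `Module.load_state_dict` but no conversion from external checkpoint
  formats is provided.
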