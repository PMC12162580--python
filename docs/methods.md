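# Methods

## Problem setting

Axial CT slices through the orbital apex contain three surgically critical
structures — the optic canal (OC, a thin bony ring), the internal carotid
artery (ICA, a bright contrast-enhanced disc) and the sphenoid sinus (SS, a
dark air-filled cavity) — plus, in trauma patients, optic-canal fractures
visible as wall discontinuity, displacement or fragmentation.  The toolkit
covers two tasks over such slices: semantic segmentation of
{background, OC, ICA, SS}, and evaluation of four-category fracture
detections (Fracture/Non-fracture × Right/Left side).

## The network family

The segmenter is a five-level encoder/decoder UNet.  Each encoder level is
two 3×3 same-padded convolutions with ReLU, followed by 2×2 max pooling;
channels double per level from `base_channels`.  The decoder mirrors it with
2×2 stride-2 transposed convolutions that halve the channel count, skip
concatenation, and a double convolution; a final 1×1 convolution produces
the four class scores.  Each of the five encoder→decoder connections (the
four concatenated skips plus the bottleneck path, which we count as the
fifth connection and transform in place) can be routed through one of three
modules:

* **plain** — identity, the classic UNet skip.
* **SKConv (texture enhancement, levels 1–3).**  Split: one same-padded
  convolution per kernel size (default 1, 3, 5, 7).  Fuse: the branch sum is
  globally average-pooled per channel, squeezed through a fully connected
  bottleneck of width `max(C / reduction_ratio, min_bottleneck)` (defaults
  8 and 16) with ReLU, then expanded to one score per (branch, channel).
  Select: a softmax across branches yields per-channel selection weights
  (nonnegative, summing to 1) and the output is the weighted branch sum.
  The module adapts its effective receptive field per channel, which is the
  mechanism that exploits texture differences at high resolution.
* **TEB (semantic perception, levels 4–5).**  The feature map is tokenised
  into non-overlapping patches (patch size 1 on the coarse maps, so one
  token per position), given learned position terms, and passed through
  `depth` (default 2) pre-norm transformer blocks: layer norm → multi-head
  self-attention (default 4 heads) with residual, then layer norm → 2-layer
  MLP with expansion `mlp_ratio` (default 4) and residual.  Attention rows
  are probability vectors by construction.  Self-attention supplies the
  long-range context that stacked small convolutions lack.

Both modules preserve the feature-map shape exactly, so the four ablation
variants — `base` (all plain), `sk` (SKConv on levels 1–3), `teb` (TEB on
levels 4–5), `improved` (both) — are drop-in reroutings of one backbone.

Reading note: "first three" plus "last two" skip connections implies five
connections, hence a depth-5 network; a classic depth-5 UNet concatenates
only four skips, so we treat the bottleneck path as the fifth connection
and apply its module before decoding.  The SK fuse widths (reduction 8,
floor 16) and all TEB sizes are the smallest common settings from the
SKNet/ViT lineage; none are dictated by the task and all are in the specs.

## Numerical backend

No deep-learning framework is assumed: the networks run on a compact
reverse-mode autodiff engine over numpy (`apexseg.nn`).  Convolutions are
im2col + BLAS matmul; their backward pass uses the transposed-convolution
and column-matmul identities.  The 2×2 transposed convolution is
non-overlapping and therefore an exact tensordot/reshape; max pooling routes
gradients to the first maximum on ties.  Everything runs in float32 for
training (float64 in the gradient-correctness tests, which check every
primitive against central finite differences).

Initialisation is He-normal, drawn per parameter name from a seed sequence
keyed by (seed, crc32(name)).  Because names of shared layers coincide
across variants, any two variants built from one seed start with
bit-identical backbone weights — the controlled-ablation property is a
consequence of the naming scheme, not of copying.

## Training

Adam (β₁ 0.9, β₂ 0.999), default learning rate 1e-3 exposed in
`TrainConfig`; the benchmark configuration uses lr 3e-3 with batch size 4,
which converged fastest at desk scale.  Loss options: pixel cross-entropy
(default), soft Dice (smoothing 1), or their sum ("combined").  The
benchmarks use the combined loss because the optic-canal ring is two to
three pixels thin and pure cross-entropy under-weights it.  Batch order and
augmentation draws derive from the config seed; two runs with the same
(spec, dataset, config) are bit-identical.  Validation mIoU is the mean IoU
of the three foreground classes with pixel counts pooled over the held-out
split.

Prediction is the per-pixel argmax of the score map; numpy's argmax breaks
ties toward the lower class index, so an all-constant score map yields
all-background.

## The phantom generator

Clinical data is private, so every experiment runs on synthetic slices that
keep only the statistical structure the tasks need.  Per side (patient
right is drawn on the image left): an SS ellipse (semi-axes ≈ 0.105·s ×
0.135·s at image side s), an ICA disc (radius ≈ 0.048·s) touching the
sinus' lateral border, and an OC ring (outer radius 0.078·s, wall
max(2.2 px, 0.036·s)) superior-lateral to the sinus, each with ±1.5 px
seeded jitter.  A fracture (drawn per side with the configured probability,
default 0.5 — dataset totals in the source data suggest a high prevalence
but no per-image rate, so this is a free parameter) cuts a 60–90° angular
gap (≥ 2 px of arc) out of the ring and deposits a displaced fragment
rectangle outside the gap; the side's box covers ring plus fragment with a
2 px margin and carries the fracture/non-fracture category.

Intensities are per-class means plus two class-specific signals: a
band-limited texture field (white noise Gaussian-filtered at a per-class
correlation length, unit-variance, scaled by `texture_contrast`) and global
Gaussian sensor noise.  Two families are fixed in `apexseg.benchmarks`:

* **easy** — distinct means (background 0.40, OC 0.78, ICA 0.92, SS 0.08),
  texture contrast 0.20, noise 0.02: separable by intensity alone.
* **texture-confusable** — all three structures share mean 0.55 against
  background 0.45; only the texture grain differs (correlation lengths SS
  6.0, background 3.0, OC 1.0, ICA 0 = white).  Multi-scale texture
  sensitivity is the discriminating capability, which is what makes the
  SKConv contribution observable.

What the phantoms do *not* emulate: Hounsfield calibration, partial-volume
effects, anatomical variability beyond jitter, 3-D continuity, indirect
fracture signs (sinus fluid/air).  Passing benchmarks therefore demonstrate
that the implementation can learn and that the modules behave as designed —
not clinical performance.

## Evaluation calculus

Segmentation: TP/FP/FN/TN by exact pixel-set arithmetic per class;
IoU = TP/(TP+FP+FN), Dice = 2TP/(2TP+FP+FN); the empty-vs-empty case
returns 1 by convention (config-exposed).  Per mask pair
Dice = 2·IoU/(1+IoU) exactly, hence Dice ≥ IoU always.  mIoU/mDice average
an explicit class set; the default excludes background (k = 3), a
`include_background` mode averages k = 4.  Test sets aggregate either
macro-over-images (default) or by global count pooling.

Detection: greedy confidence-descending one-to-one matching per category at
IoU ≥ 0.5 (the standard convention; the threshold is part of the metric's
definition, the matcher is ours to fix).  Precision, recall and
F1 = 2PR/(P+R) = 2TP/(2TP+FP+FN) with zero denominators mapping to 0.  The
PR curve sweeps the confidence-sorted list; AP integrates the precision
envelope exactly (all-point interpolation; an 11-point mode exists); mAP is
the unweighted category mean.  AUC is the normalised Mann–Whitney U with
midrank ties, implemented directly because the tie convention is part of
the contract (scikit-learn is the independent cross-check in the tests).
The paired reader comparison wraps `scipy.stats.ttest_rel` behind an
explicit zero-variance guard.  TN-based quantities appear only in the
per-side binary diagnosis task (highest-confidence category per side; an
undetected side counts as non-fracture).

Reference operating points (four-category detector, five-reader study) are
stored in `apexseg.benchmarks` and used solely to check the metric
*identities* — that the printed F1 cells equal the harmonic mean of the
printed precision/recall to three decimals, and the overall mAP equals the
per-category mean.  Published per-class segmentation tables from the same
source are internally inconsistent (one row prints Dice < IoU, which no
per-pair or averaged computation of these formulas can produce), so they
are never used as numeric oracles; only directional ordering claims are
exercised, stochastically, on phantoms.

## Problem sizes and budgets

Benchmarks run at 64×64 with `base_channels` 4 (≈ 280 k parameters for the
improved variant): large enough for the geometry, small enough that one
training run takes one to three minutes on one CPU.  The easy benchmark
trains 3 seeds × 18 epochs on 200 slices (8:2 split); the texture benchmark
trains base and sk variants 3 seeds × 14 epochs on 120 slices.  The
acceptance thresholds (mIoU ≥ 0.90 on ≥ 2 of 3 seeds; mean mIoU(sk) >
mean mIoU(base)) are stochastic properties of these fixed conditions, not
tuned quantities.

## Known limitations

* The engine is single-threaded numpy; it is a correctness-first research
  implementation, not a performance library.
* Phantom realism is deliberately minimal (see above).
* The toy detector is a ground-truth perturber for pipeline exercise; the
  toolkit evaluates detections from any source but does not train one.
* TEB position terms are sized to the build-time input side; feeding a
  different image size to a TEB variant requires rebuilding.
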