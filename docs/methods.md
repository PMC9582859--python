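# Methods

This note documents the models, losses, numerical choices and known
limitations of the package. It is the companion to the README's user-facing
description.

## Problem setting

The package diagnoses plant anomalies in RGB field images of paprika
(*Capsicum annuum*). Six anomaly classes are modeled: four viral/fungal
diseases — blossom end rot (BR), Cercospora leaf spot (CP), gray mold (GM),
powdery mildew (PM) — and two insect/pest damages — snails and slugs (SS),
spider mite (SM). Each disease carries within-class severity stages
reflecting lesion development (BR 3, GM 2, PM 2, CP 4; 11 stages total,
catalog order br1..br3, gm1..gm2, pm1..pm2, cp1..cp4 with IDs 1..11).
Pest damage has no severity grading.

The system answers three questions per image — *what*, *where*, and *how
severe* — with a single jointly trained network:

1. **Detector/localizer (DDL):** a compound-scaled convolutional backbone of
   squeeze-excitation inverted-residual blocks emits seven feature levels
   C_0..C_6 at strictly doubling strides 2..64; 3×3 convolutions reduce
   C_1..C_6 to a constant width and a weighted bi-directional feature
   pyramid (BiFPN) fuses them into P_1..P_6. Class and box subnetworks with
   parameters shared across levels predict, for N_a = 4 anchors per cell,
   per-class sigmoid probabilities and anchor-relative box offsets.
2. **Severity analyzer (DSA):** a four-stage encoder consumes C_0 plus
   pyramid levels routed by a *coupling strategy*, with a parallel-dilation
   context module at the bottleneck, attention-gated (DAM) skip connections
   and a four-stage decoder producing per-pixel logits over 11 severity
   stages plus one background channel (softmax).
3. **Integration unit:** connected severity components inside each
   detection box become uniquely-ID'd instances; instances are rendered as
   phrases such as `1: stage 3 Cercospora` and an annotated overlay. Scenes
   whose detections are all pests skip the DSA forward pass entirely
   (the *pest shortcut*).

## Architecture details and conventions

* **Level geometry.** C_0 is the stem convolution output (stride 2); block
  groups 1..6 double the stride each (2, 4, 8, 16, 32, 64), so pyramid
  level l corresponds one-to-one to backbone level b. Inputs are padded so
  all strides divide exactly. The published backbone's stride pattern
  repeats one resolution; the strictly-doubling pattern used here is the
  geometry that makes one-level-per-stride pyramids exact.
* **Channel scaling.** Widths scale by `width_mult` with rounding to
  multiples of 8, never below 90% of the unrounded value; depths by
  `depth_mult` with ceiling. The `b3` preset (width 1.2, depth 1.4,
  C_bifpn 224, M_bifpn 3, M_class = M_box = 4, M_seg 2) mirrors the
  published budget; the `tiny` preset (stem 8, C_bifpn 16, single BiFPN
  repeat, single-conv subnets, encoder widths 16/24/32/40) is the CPU-scale
  configuration used in all tests.
* **BiFPN fusion.** Fast normalized fusion: per-edge weights are
  ReLU-rectified and divided by their sum plus eps = 1e-4, so coefficients
  lie in [0,1] and sum to ≤ 1 (= 1 at eps → 0); each node applies a
  depthwise-separable convolution afterwards. Upsampling is nearest
  neighbor, downsampling stride-2 max pooling.
* **Anchors and assignment.** Anchor base size = 4 × level stride, scales
  {1, √2} × ratios {1:1, 2:1} (N_a = 4). Anchors with max-IoU ≥ 0.5 are
  positive, < 0.4 negative, in between ignored; every ground truth is
  force-matched to its best anchor. Decoding: score threshold 0.25,
  per-class NMS at IoU 0.5, top-100.
* **Coupling strategies.** `exp1` routes P1→E1, P2→E2, P3+P4→E3, P5+P6→E4
  (elementwise sum); `exp2` the same with channel concatenation; `exp3`
  P1,P2,P3,P5; `exp4` (default) P1,P2,P4,P6; `decoupled` routes nothing.
  Stage 1 joins C_0 with its routed level by concatenation and applies a
  single stride-2 convolution; stages 2..4 apply an SE-inverted-residual
  block then a stride-2 convolution, so E_1..E_4 sit at strides 4..32.
* **Decoder resize rule.** Written naively, the decoder recursion would
  concatenate maps of different grids; here each stage bilinearly resizes
  the coarser operand up to the skip's grid before concatenation — that
  resize *is* the per-stage ×2 upsampling — leaving the final decoder map
  at stride 4, where M_seg = 2 convolutions and a 1×1 prediction produce
  logits that are bilinearly upsampled ×4 to the input resolution.
* **Background channel.** Severity masks are sparse, so prediction is a
  softmax over 11 stage channels plus one explicit background channel
  (a per-stage sigmoid would leave background undefined).
* **DAM.** Additive attention gate: 1×1 projections of skip and (resized)
  gating signal, summed, ReLU, 1×1 to one channel, sigmoid, broadcast
  multiply. PDC dilation rates default to {1,2,4,8} ({1,2,4} in `tiny`).

## Losses and training

* **Classification:** focal loss, α = 0.25, γ = 1.8, on per-anchor sigmoid
  probabilities, summed over anchors and classes and normalized by the
  positive-anchor count. The final class-prediction bias is initialized to
  the prior logit (π = 0.01).
* **Box regression:** smooth-L1 (β = 0.1) on positive anchors' offsets
  (center shift / anchor size, log size ratios), averaged over positives.
* **Severity:** focal-Tversky loss on softmax probabilities with α = 0.3
  (false positives), β = 0.7 (false negatives — missed lesion pixels are
  penalized harder), γ = 4 in the exponent form Σ_c (1 − TI_c)^(1/γ), with
  smoothing 1e-6 so classes absent from both sides contribute exactly 0.
  The fractional power has an unbounded derivative at 0; contributions with
  1 − TI below 1e-6 are hard-zeroed with finite gradients.

  The exponent convention (1/γ vs γ) is not fixed by the loss's published
  uses; both were implemented and compared on the overfit benchmark. The
  1/γ form keeps per-class gradients alive as TI → 1, which is what
  disciplines the large background class and preserves rare stages — it
  produces far better masks (mIOU ≈ 0.8 vs ≤ 0.5 for the γ form) and is the
  form shipped. Its known cost: the *value* of the loss has an additive
  floor (any class with soft TI ≤ ~0.9999 contributes ≥ ~0.3), so the total
  training loss plateaus at a substantial fraction of its initial value even
  when detection is perfect and masks are excellent; convergence should be
  judged on mAP/mIOU, not on the raw focal-Tversky value.
* **Total:** λ_cls·L_cls + λ_reg·L_reg + λ_seg·L_seg with λ = 1 each (the
  weighting is not documented for the published system).
* **Batching:** epoch-shuffled (every training scene visited once per
  epoch). On few-scene datasets this keeps rare severity stages in steady
  gradient rotation; iid sampling with replacement measurably increases the
  chance that a stage present in a single scene is lost.
* **Optimization:** SGD with momentum 0.9, L2 weight decay 5e-4, linear
  warmup then cosine decay. The `paper` preset keeps lr 0.08, 3K warmup,
  batch 3, 100K iterations (GPU-scale; not exercised on CPU). The `tiny`
  preset — lr 0.01, 50-iteration warmup, batch 2, ≤ 1K iterations — is the
  tested path. Gradients are clipped to global norm 10. A non-finite loss
  aborts with a diagnostic naming the offending batch.
* **Normalization:** per-channel mean/std of the training set, stored in
  the checkpoint.

## Numerical engine

No deep-learning framework is a dependency: the networks run on a small
reverse-mode automatic-differentiation engine over numpy arrays
(`diana.nn`), providing exactly the operations the architecture needs
(dense/depthwise convolution via BLAS-backed kernel-offset sums, max
pooling, nearest/bilinear resizing as separable dense operators, batch
normalization, softmax, concatenation). Every backward rule is verified
against central finite differences in float64; training runs in float32.
Determinism: given a seed, data generation, batching and initialization are
reproducible bit-for-bit on one CPU (floating-point reduction order fixed).

## Synthetic scenes

Field imagery of diseased paprika is not redistributable, so the package
generates phantom scenes with exactly known annotations:

* Background: green foliage tones with low-frequency mottling, neutral
  distractor blobs and pixel noise scaled by a clutter level in [0,1]
  (default 0.5).
* Lesions: wobbled superellipses. Each class owns a hue band (background
  green ≈ 0.30 is avoided), each stage within a class an intensity ramp
  (value 0.30 → 0.85), with a Gaussian-blurred alpha edge (default 1.5 px)
  emulating fuzzy lesion boundaries. Mask labels follow the crisp pre-blur
  support, so the boundary band is intrinsically ambiguous — as in real
  severity annotation.
* Class frequencies default to the six classes' instance proportions in the
  field survey being emulated (BR .153, CP .285, GM .121, PM .153, SS .174,
  SM .114); lesion areas mix the survey's small/<32², medium/[32²,92²] and
  large/>92² px bins at 0.35/0.45/0.20. Crowded scenes fall back to smaller
  bins via a packing-aware cap; an over-full request raises after retries.
* Pest instances render boxes but never mask labels. Instances never touch,
  so mask components map one-to-one onto annotations.
* Determinism: one generator stream per scene, seeded by
  (global seed, scene index); datasets carry an exact 70/10/20
  train/val/test split.

What the phantom scenes do **not** emulate: photorealistic texture, leaf
venation and occlusion by plant organs, specular lighting, within-stage
appearance drift, or co-occurring overlapping infections. Passing the test
suite therefore demonstrates the pipeline's correctness and trainability,
not field-ready accuracy.

## Evaluation

PASCAL-style all-point-interpolated AP at IoU 0.5 and COCO-style AP
averaged over 0.50:0.05:0.95; size-stratified AP over the area bins above
(closed lower bound at 32²); pixel mIOU per stage (mean over classes
present in ground truth or prediction; background excluded); panoptic
quality per stage with segments matched at IoU > 0.5 (DQ is the F1 of
instance matching, SQ the mean IoU over matches — reported 0 with a flag
when there are no matches — and PQ = DQ·SQ, an identity asserted to 1e-12);
detection and pixel confusion matrices with an explicit background
row/column; PR curves at all score thresholds. AP, NMS and PQ are each
cross-checked against independent brute-force implementations in the test
suite.

## Problem sizes in the test suite

The suite and the acceptance script run on one CPU: the overfit benchmark
trains the `tiny` preset on eight 128×128 scenes of 2–4 instances each
(so each severity stage present has adequate pixel support) for 1,000
iterations (~4-5 minutes); metric oracles use ≥200 randomized instances on
64×64 grids; shape contracts cover all five coupling strategies and
randomized tiny backbone configurations.

## Known limitations

* The `paper`-scale configuration (C_bifpn 224, 100K iterations) is
  provided for completeness but is far beyond CPU budgets; no claim is made
  about reproducing the published accuracy, which also requires the
  original (unreleased) dataset.
* Training currently expects a single image size per run.
* The focal-Tversky loss value is not a convergence diagnostic (see above).
* A pure Tversky-family loss cannot revive a class whose softmax
  probability has collapsed (the gradient scales with p(1−p)); on a
  minority of initialization seeds a severity stage present in a single
  training scene is lost during the 1,000-iteration overfit run, lowering
  mIOU from ~0.9 to 0.4–0.7. Production pipelines typically mix in a
  cross-entropy term to remove this failure mode; it is omitted here to
  keep the severity loss exactly as configured.
* Checkpoints embed the full configuration but not the RNG state; resuming
  re-derives the schedule from the stored step.
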