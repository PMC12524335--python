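# Methods

`flockdetr` implements a lightweight, NMS-free, query-based detector
for dense poultry-face scenes, together with the data tooling and
metrics needed to study it end to end on a single CPU. This note
records the model, the design decisions taken where the design was
genuinely open, the numerical choices, and what the synthetic
benchmark does and does not demonstrate.

## The detector

The architecture follows the hybrid-encoder family of real-time
detection transformers: a convolutional backbone emits feature maps at
strides 8/16/32; an intra-scale attention stage operates on the
stride-32 level only; a cross-scale fusion pyramid (top-down then
bottom-up, CSP-style fusion blocks) mixes the three levels; and a
query decoder converts the fused tokens into a fixed set of
box/score pairs. Inference is a pure function of the per-query
outputs: thresholding and sorting, no non-maximum suppression.

### Dynamic inception depthwise convolution

The backbone's token mixer runs three depthwise branches over the
input `V` — a `k x k` square kernel and two strip kernels `1 x b` and
`b x 1` with `b = 3k + 2` (default `k = 3`, so `b = 11`) — and fuses
them with input-conditioned weights:

    U  = GAP(V)                       per-channel global context
    S  = Conv1x1(U)  in R^{3C}
    a_i = softmax_i(S_i)              a simplex over the 3 branches
    Y  = SiLU(BN(a_1 F_1 + a_2 F_2 + a_3 F_3))

The strips give elongated receptive fields for stretched or partially
occluded birds; the gate lets each channel choose its mixture per
image. Branches are depthwise only; all channel mixing lives in the
surrounding unit: a dual-residual mixer `X + TokenMix(X)` followed by
`+ GatedChannelMLP(.)`, where the gated MLP is a convolutional gated
linear unit (pointwise expand x2, split value/gate, depthwise-3x3 +
sigmoid gate, pointwise project). Mixers sit as bottlenecks inside a
C2f-style split/concat block. The 1x1 gate map has a bias and no
activation before the softmax — the simplest map consistent with the
design. The square kernel is odd so "same" padding is symmetric.

Open point resolved: whether BN/SiLU apply per branch or after the
sum. The single post-sum BN + SiLU is used, which keeps the fused
operator exactly equal to the explicit composition tested against the
step-by-step oracle.

### Polar linear-attention encoder stage

The stride-32 stage replaces softmax attention with kernelized linear
attention whose nonnegative feature map factors into a radial
(magnitude) gain and an angular (direction) projection per head:

    phi(z) = softplus(r) * (elu(z W_ang) + 1)
    out_i  = phi_q(q_i) (sum_j phi_k(k_j) v_j^T)
             / (phi_q(q_i) sum_j phi_k(k_j) + eps)

`elu(.) + 1` guarantees nonnegativity; `softplus(r)` is the learnable
radial profile. Cost is `O(N d^2)` rather than `O(N^2 d)`; the suite
verifies equivalence with the explicit dense normalization to 1e-4
for `N <= 16` and the 2x MAC scaling when `N` doubles. This
factorization is an interpretation of "polar-coordinate attention" —
it is the component most likely to differ from any reference
implementation, and the contracts tested are the ones stated here.

Around the attention sit, in fixed order: DynamicTanh normalization
(`g * tanh(a x) + h`, per channel, no batch statistics; `a` initialized
to 0.5), a multi-scale adapter (down-project to 1/4 width, parallel
depthwise 3/5/7 + average-pool branches fused by a 4-way
input-conditioned simplex gate, up-project, learnable scaled
residual), a detail feed-forward network (pointwise expand x2, GELU,
parallel depthwise 3x3/5x5 fused by a 2-way gate, pointwise project)
with a residual and dropout in the caller, a second DynamicTanh, and a
second, independently-weighted adapter. Residual-path dropout defaults
to 0 (evaluation parity); 0.1 is the training suggestion. The two
adapters do not share weights.

### Matchability-aware classification loss

Queries and ground truth are matched one-to-one by a Hungarian
assignment under `cost = 2 (1 - p) + 5 ||b - b*||_1 + 2 (1 - GIoU)`.
With `q` the IoU of the matched pair (treated as a constant target)
and `y` the binary match label, the classification loss is

    L(p, q, y) = -(q^g log p + (1 - q^g) log(1-p))   y = 1
                 -p^g log(1-p)                        y = 0

with a single focusing parameter `g = 2`. The positive branch is a
soft-label cross-entropy minimized at `p = q^g`, so confidence tracks
a sharpened copy of localization quality; the negative branch focuses
on confident false positives, with no class-balance hyperparameter.
The varifocal alternative (`-q (q log p + (1-q) log(1-p))` positive,
`-0.75 p^2 log(1-p)` negative) is retained for comparisons; slide-loss
variants are recognized in configuration but deliberately rejected.
The composite objective adds `5 L1 + 2 (1 - GIoU)` box terms on
matched pairs, normalized by the number of matches in the batch, and
is applied at the encoder proposal stage and at every decoder layer.

### Decoder

Three standard post-norm transformer layers (8 heads, FFN width 384)
over 300 queries seeded from encoder proposals: every fused token
predicts a score and a box around its grid anchor (anchor size
0.05 x 2^level), the top-K tokens by score provide query content and
reference boxes, and each layer refines references through
inverse-sigmoid deltas with detached iterative refinement. Cross
attention is dense softmax attention over all pyramid tokens with a
parameter-free Gaussian locality bias `-(||t - c_i||^2 / (2 s_i^2))`
centred on each query's reference box (`s_i^2 = w_i h_i / 4`). The
bias plays the role deformable sampling plays in the reference
designs — it makes each query's read local from the first step —
without sampling kernels, which the numpy engine does not provide.
Memory tokens and query references share one normalized-coordinate
sinusoidal position embedding, so the two sides of cross-attention
live in the same geometry.

Initialization matters at small step budgets: attention output
projections, the decoder FFN's second linear, and the last layer of
every box head start at zero (each residual block is the identity at
initialization, preserving per-query diversity), and score-head
biases start at logit(0.01). Without the zero-init the decoder's
query contents collapse to a common vector within two layers and
training stalls; with it the toy benchmark converges in a few
hundred steps.

## Architecture budget calibration

The toolkit targets published architecture-level budgets: full model
13.3 M parameters / 43.8 G FLOPs at 640 x 640, baseline (plain
residual backbone + softmax-attention stage + varifocal loss) 19.9 M /
56.9 G, and the mixing-backbone-only variant 13.2 M. Only totals are
published, so interior widths and depths were solved once against
those five constraints and frozen: mixing backbone depths (1,1,2,1)
with split ratio 0.5332; baseline backbone depths (1,3,2,1), stem 85,
residual inner width 1.043 x C; fusion concentrated at the stride-8
level (three residual blocks at width 279); intra-scale FFN width 934
in the baseline stage; decoder FFN 384. The calibration is pure
arithmetic on parameter/MAC counts — no training is involved — and
the acceptance script recomputes all four totals from scratch.

FLOPs follow the multiply-accumulate convention that dominates
detection papers' "G" figures: `k_h k_w (C_in/g) C_out H_out W_out`
per convolution, one MAC per element of every matrix product
(attention cores included), elementwise work uncounted. The profiler
gathers counts from the shapes seen during a single forward pass.

## Synthetic data

The paper-scale imagery this family of detectors targets is not
public, so the generator renders the study conditions: elliptical
"faces" (feathered ellipse, comb bumps, eye dot, beak wedge) over
textured litter backgrounds, in three growth-stage regimes —
brooding (face scale 3.5–8% of the image side, 12–22 per scene),
growing (7–15%, 6–12), finisher (13–26%, 3–7). Faces render
back-to-front so later faces occlude earlier ones; the `occlusion`
level bounds the pairwise IoU of face boxes allowed during placement
(0 forces disjoint faces, with bounded-retry best-effort placement).
Boxes are the exact extents of each instance's visible pixels taken
from the ownership map, so they match the rendered masks bit for bit.
Global gamma and noise apply after boxes are fixed.

What the generator does not emulate: real feather texture, pose
variation beyond in-plane rotation of the ellipse axes, camera blur
and night-vision artifacts, inter-bird appearance correlation, and
annotation noise. Passing the recovery benchmark therefore shows that
the training pipeline (matching, losses, optimization, decoding) can
recover well-separated synthetic targets; it says nothing about
accuracy on real farm imagery.

The augmentation suite mirrors barn nuisances: rotation +-45 deg
(axis-aligned hull of rotated corners, black fill, sub-pixel boxes
dropped), salt-and-pepper noise at 0.5–3% density, and gamma 0.5–1.5
combined with +-20% HSV-value scaling. Training-set expansion draws
sources with replacement and picks one strategy uniformly per extra
image. Splits are 8:1:1 with floors on val/test and the remainder to
train.

## The recovery benchmark

The CPU-scale check trains the reduced profile (backbone widths
16/32/48/64, embed dim 64, 30 queries, 2 decoder layers, 160 x 160
input, AdamW lr 1e-3, batch 8) on 200 easy scenes — finisher-stage
faces, one to three per image, zero occlusion budget — for 10 epochs,
evaluating held-out mAP@0.5 on 50 scenes each epoch; three seeds per
loss. Ten epochs sit well past the observed convergence point
(roughly epoch 4–6) while keeping the six-run comparison inside a
practical suite runtime. The matchability-aware arm must average
>= 0.8 held-out mAP@0.5 (observed ~0.99); the convergence-epoch
comparison against the varifocal arm (first epoch within 2% of the
final mAP) is reported as measured. At this easy scale both losses
converge within a few epochs, so small differences between them are
not evidence about full-scale convergence behaviour.

## Numerical choices and degenerate inputs

* Engine dtype is float32 throughout; probabilities are clamped to
  `[1e-7, 1 - 1e-7]` (the smallest float32-effective gap at 1) with
  pass-through gradients strictly inside the bounds.
* Batch norm: momentum 0.1, eps 1e-5; oracle tests run eval-mode BN
  with frozen statistics for determinism.
* GIoU of a zero-area box is IoU 0 plus the enclosure penalty; box
  intersections clamp at zero width/height.
* Greedy detection/ground-truth matching for P/R/F1 proceeds in
  descending score order, each ground-truth box claimable once, ties
  broken by best IoU. AP uses the 101-point interpolation of the
  precision-recall integral; mAP@0.5:0.95 averages IoU 0.50 to 0.95
  in steps of 0.05. Empty denominators yield 0 by convention.
* The Hungarian assignment uses `scipy.optimize.linear_sum_assignment`
  and is verified against exhaustive enumeration for small instances.
* FPS is `1000 / (T_pre + T_inf + T_nms)` with times in milliseconds
  and `T_nms = 0` for this NMS-free detector; wall-clock FPS is
  measured but never asserted, being hardware-dependent.
* Checkpoints are `.npz` archives of the flat parameter/buffer state
  plus the fully resolved configuration, so save -> load -> forward is
  bitwise reproducible in eval mode.

## Known limitations

* The engine is a compact numpy autodiff implementation: single
  threaded apart from BLAS, no GPU, no mixed precision; full-scale
  (640 px) training is out of practical reach, which is why the
  recovery benchmark runs the reduced profile.
* The polar attention factorization and the locality-biased dense
  cross-attention are principled stand-ins for components whose
  reference formulations are not fully specified; their contracts
  (equivalence, linearity, simplex gating) are tested, their exact
  arithmetic is this package's own.
* Budget calibration fixes interior widths against published totals;
  other width/depth splits could meet the same totals.
* The synthetic benchmark's "easy" regime is deliberately easy; dense
  brooding-stage scenes with heavy occlusion are generated and tested
  for geometric fidelity but are not part of the recovery criterion.
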