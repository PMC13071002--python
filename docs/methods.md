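# Methods

`orchardet` implements the building blocks of an occlusion- and
density-aware small-object detector for orchard imagery, together with
a synthetic test bed that makes every mechanism verifiable on CPU.
This note records the models, the defaults and why they were chosen,
the numerical conventions, and the limits of what the synthetic
experiments demonstrate.

## Condition maps

Two single-channel rasters in [0, 1] summarize what makes orchard
scenes hard: canopy occlusion and fruit clustering.

**Density map.** One isotropic Gaussian per annotated fruit center,
with a geometry-adaptive bandwidth

    sigma_i = clamp(beta * dbar_i, sigma_min, sigma_max)

where `dbar_i` is the mean center-to-center distance to the `k`
nearest other fruits. Defaults `k = 3`, `beta = 0.3`,
`sigma_min = 1 px`, `sigma_max = 15 px` follow the crowd-counting
convention for geometry-adaptive kernels; tighter clusters get sharper
kernels, monotonically, down to `sigma_min`. Kernels are discrete unit
Gaussians (integral within 1% of 1 for sigma <= 8 px), truncated at 4
sigma, sampled at integer pixel indices so that an exactly centered
annotation peaks at a single unambiguous pixel. The summed raster is
divided by `max + 1e-6`, so values lie in [0, 1). Maps are produced at
full image resolution (640 px in the default regime) and area-pooled
to feature scales.

**Occlusion map.** Computable from the image alone (no annotations),
as an equal-weight combination of

* *contrast attenuation*: `1 - s_local / (s_global + eps)` with
  `s_local` the grayscale standard deviation in a 7x7 window — flat
  overpainted regions (leaves) lose local variance relative to the
  scene; and
* *edge discontinuity*: Sobel gradient magnitude, max-normalized.

Both terms are ratios, so the map is invariant to global affine
brightness changes up to the epsilon guard; images with near-zero
global contrast return all zeros. The 0.5/0.5 weighting, the 7x7
window and Sobel gradients are this module's canonical definition of
the two analyses.

**Pooling.** Area-average pooling assigns each source pixel to exactly
one target cell (`floor(i * target / source)`), so pooled values stay
inside the input's range for any resolution ratio.

## Condition-Guided Windowed Attention (CGWA)

Multi-head self-attention inside non-overlapping `Ws x Ws` windows
(default `Ws = 7`, 4 heads), computing per window

    A_enh = softmax(alpha(O, D) * (Q K^T / sqrt(d_k)) + B + beta(O, D)) V

* `B` is a learned relative position bias with `(2 Ws - 1)^2` entries
  indexed by query-key displacement (translation-equivariant within
  the window).
* `alpha(O, D)` in (0, 1), one factor per head per window, from a
  two-layer MLP (hidden 16, ReLU, dropout in train mode, sigmoid) fed
  with the window's mean occlusion and density. It multiplies the
  *scaled* logits (after the `sqrt(d_k)` division). No setting of the
  MLP is neutral (the sigmoid cannot emit 1), so exactness tests
  freeze the factor at a known constant rather than seeking an
  identity configuration.
* `beta(O, D)` in (0, 1), a two-layer convolution (2→8→1, sigmoid)
  over the concatenated rasters, added per *key* position — boundary
  cells attract attention. A constant beta shifts every key logit
  equally and cancels in the softmax, which is why zeroed boundary
  weights are exactly neutral.
* Both rasters are first refined by parallel three-layer convolutional
  encoders (1→8→16→1, sigmoid); widths are this package's choice, the
  depth is fixed at three. The refined rasters feed both the
  modulation MLP and the boundary network.

Windows that overhang the grid are zero-padded; padded cells get -1e9
key logits, hence exactly zero attention mass. The output projection
is zero-initialized, so a freshly built block is the identity — it can
be inserted into a working graph without perturbing it, and the
property doubles as an exact regression test. Score memory is
`Ws^4 * (H/Ws) * (W/Ws) * heads` entries rather than `(H W)^2`.
Shifted windows and cross-window communication are out of scope.

## Attention-guided Space-Preserving Convolution (ASPC)

A downsample-by-two stage that discards nothing:

    F_out = M_ch * (M_sp * Conv3x3(SPD(F_in)))

`SPD` rearranges each 2x2 spatial block into four channel groups in
the fixed order (top-left, top-right, bottom-left, bottom-right);
it is bijective, and odd inputs are right/bottom zero-padded first so
the round trip stays exact on the padded grid. The 3x3 convolution
maps `4C` directly to `out_channels`. The spatial gate
`sigmoid(Conv7x7([mean_c; max_c]))` is applied first and the channel
gate `sigmoid(MLP(avg) + MLP(max))` (shared bottleneck, reduction
r = 16 by default, r = 4 in the narrow test models) second — the
composition order follows the block's defining formula even though the
CBAM lineage is channel-first. Each gate is computed from the tensor
it multiplies (cascaded). Since both gates are strictly inside (0, 1),
the output never exceeds the un-gated convolution in magnitude.

## Dual-Adaptive Dynamic Upsampling (DADU)

Upsampling by grid-sampling the input at displaced positions. Two
zero-initialized branches predict offsets of shape `(B, 2 G s^2, H, W)`
— a 1x1 pointwise convolution (content-global trends) and a 3x3
convolution (local, boundary-aware) — fused by

    delta_fused = sigmoid(p) * delta_1 + (1 - sigmoid(p)) * delta_2

with the raw scalar `p` stored unconstrained and initialized to 0.5
(effective weight sigmoid(0.5) ≈ 0.622 at init; the formula applies
the sigmoid explicitly, so "initialized to 0.5" is read as the raw
parameter). Offsets are predicted in source-grid cell units and
converted to the sampler's [-1, 1] normalized coordinates. The base
grid uses the align-corners-false cell-center convention,
`x_src = (j + 0.5) / s - 0.5`, which preserves mean position at any
scale; a stray citation marker in the source text made the coordinate
range read as "(-15, 15)", which is resolved to the standard [-1, 1].
Sampling is bilinear with border replication, per channel group
(`G = 4` by default), groups concatenated along channels — this is the
reading of the group-wise sum that matches the published
`B x C x (sH) x (sW)` output shape. Optional extras: PL mode
(pixel-shuffle pre-expansion, requiring `s^2 | C`, after which offsets
refine an already-expanded grid), and dynamic scope (a zero-initialized
1x1 convolution whose sigmoid multiplies the offsets, so magnitudes
never grow and halve exactly at init). With all offset parameters at
zero the block reduces to plain base-grid resampling and is independent
of the fusion weight.

## Colorimetric maturity rules

Pixel classification by fixed HSV/RGB thresholds (hexagonal HSV, hue
on [0, 360), saturation = delta/max):

| class | hue (deg) | saturation | RGB conditions |
|---|---|---|---|
| ripe | [0, 20) or [340, 360] | > 0.6 | R > G + 15 and R > B + 15 |
| semi-ripe | [20, 60) | — | \|R − G\| <= 20 or 0 < R − G <= 30 |
| unripe | [60, 120) | [0.35, 0.85] | G > R and G > B |

Evaluation order is ripe → semi-ripe → unripe (the ripe rule is the
strictest compound condition); hue intervals are half-open above
except the wrap-around ripe interval; unmatched pixels are
*unclassified*. The semi-ripe tolerances (±20 for "approximately
equal", ≤30 for "slightly greater") are this module's fixed constants
for qualitative wording; no saturation constraint is imposed on
semi-ripe because none is stated. Box-level labels are a majority vote
over classified pixels in the box. The rules are deliberately not
learned from data, and no illumination correction is applied.

## Synthetic orchard scenes

The generator emulates the study regime: 640x640 scenes, fruits
under 32 px, three color-defined classes, heavy clustering
(inter-fruit distances below 15 px occur), and ~40% of fruits with
more than 30% visible-area occlusion. Design choices:

* Fruit colors are rejection-sampled from the interior of each
  colorimetric threshold region with margin, and required to keep
  their label under the darkest shading applied; shading is
  multiplicative (hue- and saturation-preserving), so an unoccluded
  fruit always round-trips to its generating class.
* Backgrounds and leaves stay below 0.35 saturation, outside every
  class rule.
* Occlusion is exact by construction: a leaf is placed over a fruit
  with probability `occluder_density` (default 0.45) and covers a
  circular-cap fraction drawn from U(0.15, 0.75), whose chord offset
  is solved numerically; the leaf quad covers just that cap, keeping
  spillover onto neighbors small. The default regime arithmetic:
  P(cap > 0.3) = 0.45/0.60 = 0.75, so leaves alone give
  0.45 × 0.75 ≈ 0.34, fruit-on-fruit overlap adds ≈ 0.05-0.06, and
  leaf spillover a little more — centering the >30%-occluded share
  near 0.40-0.45. Occluded fractions are measured on pixel masks
  (visible area), not box IoU, and include fruit-on-fruit coverage;
  fully hidden fruits stay annotated with fraction 1.
* Placement: cluster centers plus Gaussian spread; fruits keep center
  distance >= 0.6 (r1 + r2), which still allows sub-15 px spacing.
  Bounded retries, then an infeasible-packing error.
* Augmentation defaults mirror the published policy: flips, rotation
  ±15°, random cropping, brightness ±30%, contrast ±25%, hue ±10°,
  saturation ±30%. Geometric transforms carry the boxes (axis-aligned
  hulls under rotation, clipped, dropped under 4 px^2); photometric
  transforms never touch them.
* `write_dataset` renders to PNG + YOLO text labels + float32
  condition rasters, split 70/15/15 by largest-remainder
  apportionment (20 scenes → 14/3/3).

What the synthetic regime does *not* emulate: real foliage texture,
specular highlights, perspective and defocus, annotation noise, and
natural class imbalance. Passing tests therefore demonstrate that the
mechanisms are implemented correctly and can learn under controlled
conditions — not field accuracy on real orchards.

## Detector assembly

A compact three-scale one-stage detector (strides 8/16/32) with a
width multiplier: backbone widths (w, 2w, 4w, 8w, 8w), a
path-aggregation neck (two top-down upsamples, two bottom-up
downsamples) with 4w channels, and 1x1 heads. Toggles place the
blocks: ASPC replaces every backbone stride-2 downsample; DADU
replaces both top-down upsamples (exactly two instances); CGWA refines
each of the three neck outputs, consuming conditions pooled to that
scale. All toggles off yields a plain convolutional baseline. The
published variant's absolute parameter/GFLOP figures are not
reproducible from the text (its baseline matches no standard release),
so the reduced-width model is dimensioned for CPU training instead;
`count_params_flops` reports exact parameters and analytically counted
multiply-accumulates for whatever configuration is built.

Detection targets are anchor-free: every cell whose center falls in a
truth box (routed to one scale by box size: <20 px, <40 px, else
coarse) regresses the distances (l, t, r, b) to the box edges in
stride units, so duplicate detections of one object coincide and NMS
collapses them; overlapping boxes give the cell to the smaller box.
Losses are conventional: focal binary cross-entropy objectness
(alpha 0.25, gamma 2, normalized by the positive count) so the hard
cells ringing each object dominate the gradient, MSE on the distance
regression (weight 2), softmax cross-entropy on classes at positives.
Training clips the global gradient norm at 5, which removes the
occasional early-training instability of the attention stack.
Heads are CoordConv-style — two normalized coordinate channels are
appended to the neck features — which materially accelerates
localization learning at small step budgets. The objectness bias
starts at -4 (low prior) so training begins without a flood of false
positives.

Conditions at inference: the occlusion map comes from the image; the
density source is configurable — `offline_gt` (precomputed from
annotations, for unit tests), `predicted` (default; a 3x3-3x3 sigmoid
head on stem features trained against the offline maps with MSE), or
`uniform` (0.5, ablation).

Evaluation follows the standard protocol: greedy per-class matching
by descending score at IoU >= 0.5, one match per truth box, score and
IoU ties broken toward the lower index for bit-reproducibility; AP by
all-point precision-envelope interpolation; mAP is the unweighted
class mean; micro precision/recall/F1 over all supplied detections;
the confusion matrix (class-agnostic matching) carries a background
row for false alarms and a background column for misses. The CAM
utility is gradient-weighted: objectness logits of one scale summed,
back-propagated to that scale's neck features, channels weighted by
mean gradient, rectified and min-max normalized (uniform 0.5 fallback
for degenerate maps).

## Numerical and reproducibility conventions

* All tensors are float64; the autodiff engine is a compact
  reverse-mode tape over NumPy with hand-written conv2d (im2col) and
  bilinear grid-sample primitives, verified against finite differences
  and brute-force oracles at 1e-5/1e-6 tolerances.
* Every stochastic component takes an explicit seed
  (`numpy.random.Generator`); same seed → byte-identical scenes,
  identical training traces, identical checkpoints.
* Checkpoints are single `.npz` files with the model config embedded.
* Tie-breaks: max-gradient splits over ties; NMS and matching prefer
  the lower box index; window order never affects reconstruction.

## Problem sizes used in the shipped experiments

The statistical contract of the generator is measured over 200 scenes
at 320 px (the occlusion statistic is resolution-independent by
construction; 320 px keeps the run inside a couple of minutes on one
core). The end-to-end learning check trains the fully assembled model
(all toggles, width 8) on eight 96 px scenes of four well-separated
unoccluded fruits for 200 full-batch Adam steps at lr 0.005 — a
deliberately scaled-down memorization run that exercises every block,
the condition plumbing, the losses and the evaluator end to end.

## Known limitations

* The engine is CPU-oriented and loops over some dimensions (NMS,
  decode); it is not meant for images beyond a few hundred pixels or
  real-time use.
* The occlusion map is a hand-crafted heuristic, not a learned
  estimator; it marks flat low-contrast regions as occluding, which is
  correct for the synthetic leaves and only approximate for real
  foliage.
* The density head is trained only through its auxiliary MSE; at the
  shipped training scales its predictions are coarse.
* Ablation orderings of the three blocks are structural claims only;
  no statement is made that one block outperforms another at desk
  scale, because tiny-run mAP differences are training-noise dominated.
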