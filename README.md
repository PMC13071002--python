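# orchardet

Occlusion- and density-aware building blocks for detecting small,
clustered fruit — such as coffee cherries — in orchard imagery, with a
fully synthetic, CPU-friendly test bed.

Fruit in field imagery is hard for standard detectors for three
compounding reasons: the objects are small (often under 32×32 px at
640×640), they grow in dense clusters (center distances under 15 px),
and a large share is partially hidden by foliage. `orchardet`
implements, as independently testable components, the three
architectural mechanisms that address these failure modes, plus the
surrounding machinery needed to exercise them end to end without a
field dataset or a GPU:

* **condition maps** — a per-pixel *occlusion map* O (local contrast
  attenuation + edge discontinuity, computable from the image alone)
  and a *density map* D (geometry-adaptive Gaussian kernels at
  annotated fruit centers, crowd-counting style), both in [0, 1];
* **CGWA** — condition-guided windowed attention:
  `softmax(α(O,D)·(QKᵀ/√d_k) + B + β(O,D)) V` inside non-overlapping
  7×7 windows with a relative position bias B, a head-wise modulation
  factor α ∈ (0,1) from window-level condition statistics, and an
  additive key-side boundary bias β ∈ (0,1);
* **ASPC** — attention-guided space-preserving convolution:
  `F_out = M_ch ⊙ (M_sp ⊙ Conv3×3(SPD(F_in)))`, a lossless
  space-to-depth downsample (B×C×H×W → B×4C×H/2×W/2, bijective)
  followed by cascaded spatial and channel attention gates;
* **DADU** — dual-adaptive dynamic upsampling: two offset branches
  (1×1 and 3×3) fused as `Δ = σ(α)·Δ₁ + (1−σ(α))·Δ₂`, then group-wise
  bilinear grid sampling at `P_base + Δ` with border padding;
* **colorimetry** — the fixed HSV/RGB maturity thresholds for
  unripe / semi-ripe / ripe classification of pixels and boxes;
* **synthetic_orchard** — a deterministic scene generator with exact
  ground truth (classes, boxes, per-fruit occluded fractions) that
  reproduces the study regime (~40% of fruits >30% occluded), plus the
  standard augmentation policy (±15° rotation, crops, flips,
  brightness ±30%, contrast ±25%, hue ±10°, saturation ±30%) and a
  70/15/15 dataset writer (PNG + YOLO labels + condition rasters);
* **detector** — a reduced-width three-scale assembly with toggles for
  each block, tiny-scale CPU training, mAP@0.5 / precision / recall /
  F1 / PR-curve / confusion-matrix evaluation, analytic
  parameter/FLOP counting, and a Grad-CAM style heatmap utility.

Everything differentiable runs on a compact reverse-mode autodiff
engine over NumPy (`orchardet.nn`) in float64, with conv2d and
bilinear grid-sample primitives verified against finite differences
and brute-force oracles.

## Worked example

```python
import numpy as np
from orchardet.synthetic_orchard import SceneSpec, render_scene
from orchardet.colorimetry import classify_box
from orchardet.condition_maps import generate_density_map, generate_occlusion_map

spec = SceneSpec(image_size=320, n_fruits=10, seed=7)
image, truth = render_scene(spec)
print(len(truth.boxes), "fruits;",
      sum(f > 0.3 for f in truth.occluded_fraction), "occluded >30%")

label, share = classify_box(image, truth.boxes[0])
print("first fruit:", label.value, f"(vote share {share:.2f})")

density = generate_density_map(truth.boxes, 320, 320)
occlusion = generate_occlusion_map(image)
print("density peak", float(density.max()), "occlusion mean", round(float(occlusion.mean()), 3))
```

prints (seed 7):

```
10 fruits; 3 occluded >30%
first fruit: semi_ripe (vote share 1.00)
density peak 0.9995228505414055 occlusion mean 0.447
```

— ten fruits with three heavily occluded (the regime the generator is
calibrated to), a perfect colorimetric vote on an unoccluded fruit,
the density raster normalized into [0, 1), and a mid-range mean
occlusion score for a scene that mixes textured fruit against flat
leaf cover.

Training and evaluating the assembled detector end to end:

```python
from orchardet.benchmarks import overfit_small_scenes
result = overfit_small_scenes(seed=0, n_scenes=8, steps=200)
print(round(result["map50"], 3), round(result["loss_last"] / result["loss_first"], 3))
```

memorizes eight easy 96 px scenes with the full model (all three
blocks active) in 200 seeded Adam steps on one CPU core.

A thin CLI mirrors the library:
`orchardet generate`, `orchardet condmaps`, `orchardet classify-color`,
`orchardet train-tiny`, `orchardet eval`, `orchardet flops`.

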