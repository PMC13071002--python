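"""Deterministic synthetic orchard scenes with exact ground truth.

Scenes emulate the study regime of field imagery: 640x640 canvases of
small (< 32 px) circular fruits in three color-defined maturity
classes, clustered so that inter-fruit center distances reach below
15 px, partially hidden behind leaf-like occluders so that roughly 40%
of fruits end up with more than 30% of their area covered.  Every
quantity a detector test needs is known exactly:

* fruit colors are rejection-sampled from the *interior* of the
  colorimetric threshold regions (with margin), and shading is
  multiplicative, so an unoccluded fruit always round-trips through
  :func:`orchardet.colorimetry.classify_box` to its generating class;
* occluded fractions are measured on pixel masks (visible-area), not
  box overlap, and include fruit-on-fruit coverage;
* occluders are placed per fruit with probability ``occluder_density``
  and cover a circular-cap fraction drawn from U(0.15, 0.75), whose
  chord offset is solved exactly — this makes the occlusion statistics
  controllable by construction (see docs/methods.md for the expected
  regime arithmetic);
* rendering is a pure function of the spec's seed.

Backgrounds (flat or blobby foliage) and leaf colors are kept at low
saturation so they never satisfy a maturity color rule.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import imageio.v3 as iio
import numpy as np
from scipy.optimize import brentq
from skimage import draw as skdraw
from skimage import transform as sktransform
from skimage.color import hsv2rgb, rgb2hsv

from .boxes import BoxAnnotation, write_yolo_labels
from .colorimetry import DEFAULT_RULES, CLASS_NAMES, classify_rgb_pixel
from .condition_maps import DensityKernelParams, generate_density_map, generate_occlusion_map

__all__ = [
    "SceneSpec",
    "SceneTruth",
    "AugmentPolicy",
    "render_scene",
    "augment",
    "write_dataset",
]

_CLASS_HSV_RANGES = {
    # class id -> (hue lo, hue hi, sat lo, sat hi, val lo, val hi); sampled
    # with a margin inside the colorimetric thresholds
    0: (70.0, 110.0, 0.45, 0.78, 120.0, 200.0),  # unripe green
    1: (28.0, 55.0, 0.55, 0.85, 150.0, 220.0),  # semi-ripe yellow-orange
    2: (346.0, 372.0, 0.70, 0.92, 150.0, 220.0),  # ripe red (wraps at 360)
}
_MIN_SHADING = 0.82  # darkest multiplicative shading applied to a fruit


@dataclass(frozen=True)
class SceneSpec:
    """Declarative description of one synthetic orchard image."""

    image_size: int = 640
    n_fruits: int = 25
    class_mix: tuple[float, float, float] = (0.25, 0.35, 0.40)
    radius_range: tuple[float, float] = (6.0, 14.0)
    cluster_count: int = 4
    cluster_spread: float = 18.0
    occluder_density: float = 0.45
    background_texture: str = "foliage"  # {"flat", "foliage"}
    illumination_gain: float = 1.0
    seed: int = 0

    def __post_init__(self):
        if abs(sum(self.class_mix) - 1.0) > 1e-9:
            raise ValueError("class_mix probabilities must sum to 1")
        if self.radius_range[0] <= 0 or self.radius_range[1] < self.radius_range[0]:
            raise ValueError("radius_range must be positive and ordered")
        if self.background_texture not in ("flat", "foliage"):
            raise ValueError("background_texture must be 'flat' or 'foliage'")
        if not 0.0 <= self.occluder_density <= 1.0:
            raise ValueError("occluder_density must be in [0, 1]")


@dataclass
class SceneTruth:
    """Exact ground truth for one rendered scene."""

    boxes: list[BoxAnnotation]
    occluded_fraction: list[float]
    classes: list[int]
    occluder_mask: np.ndarray  # (H, W) bool, union of all leaf occluders


def _hsv_to_rgb255(h_deg: float, s: float, v: float) -> np.ndarray:
    rgb = hsv2rgb(np.array([[[(h_deg % 360.0) / 360.0, s, v / 255.0]]]))[0, 0]
    return np.round(rgb * 255.0).astype(np.int64)


def _sample_class_color(class_id: int, gain: float, rng: np.random.Generator) -> np.ndarray:
    """A fruit base color that keeps its class label under shading."""
    hlo, hhi, slo, shi, vlo, vhi = _CLASS_HSV_RANGES[class_id]
    want = CLASS_NAMES[class_id]
    for _ in range(200):
        rgb = _hsv_to_rgb255(rng.uniform(hlo, hhi), rng.uniform(slo, shi), rng.uniform(vlo, vhi))
        ok = True
        for scale in (1.0, _MIN_SHADING):
            c = np.clip(np.round(rgb * scale * gain), 0, 255).astype(int)
            if classify_rgb_pixel(*c, DEFAULT_RULES) is not want:
                ok = False
                break
        if ok:
            return rgb
    raise RuntimeError(f"could not sample a stable color for class {class_id}")


def _background(size: int, kind: str, gain: float, rng: np.random.Generator) -> np.ndarray:
    """Low-saturation greenery that never matches a maturity rule."""
    if kind == "flat":
        base = _hsv_to_rgb255(95.0, 0.22, 90.0)
        img = np.tile(base, (size, size, 1)).astype(np.float64)
    else:
        # smooth blobby foliage: low-res HSV noise upsampled
        n = max(size // 40, 4)
        hue = rng.uniform(70, 120, size=(n, n))
        sat = rng.uniform(0.10, 0.30, size=(n, n))
        val = rng.uniform(60, 130, size=(n, n))
        up = lambda a: sktransform.resize(a, (size, size), order=3, mode="reflect", anti_aliasing=False)
        hsv = np.stack([up(hue) / 360.0, np.clip(up(sat), 0.05, 0.32), np.clip(up(val), 0, 255) / 255.0], axis=-1)
        img = hsv2rgb(hsv) * 255.0
    return np.clip(img * gain, 0, 255)


def _cap_chord_offset(radius: float, frac: float) -> float:
    """Signed chord distance so the circular cap covers ``frac`` of the disk."""

    def cap_fraction(d):
        return (radius**2 * np.arccos(np.clip(d / radius, -1, 1)) - d * np.sqrt(max(radius**2 - d**2, 0.0))) / (
            np.pi * radius**2
        )

    return brentq(lambda d: cap_fraction(d) - frac, -radius + 1e-9, radius - 1e-9, xtol=1e-6)


def render_scene(spec: SceneSpec) -> tuple[np.ndarray, SceneTruth]:
    """Render one scene; identical specs yield byte-identical results."""
    rng = np.random.default_rng(spec.seed)
    size = spec.image_size
    img = _background(size, spec.background_texture, spec.illumination_gain, rng)

    # --- place fruits (cluster centers + spread, bounded overlap) ---------
    margin = spec.radius_range[1] + 2
    n_clusters = max(spec.cluster_count, 1)
    centers = rng.uniform(margin, size - margin, size=(n_clusters, 2))
    fruits = []  # (cx, cy, r, class_id)
    attempts = 0
    while len(fruits) < spec.n_fruits:
        attempts += 1
        if attempts > 60 * max(spec.n_fruits, 1):
            raise RuntimeError(
                f"infeasible packing: placed {len(fruits)}/{spec.n_fruits} fruits "
                f"after {attempts} attempts"
            )
        cl = centers[rng.integers(n_clusters)]
        r = rng.uniform(*spec.radius_range)
        cx, cy = cl + rng.normal(0.0, spec.cluster_spread, size=2)
        if not (margin <= cx <= size - margin and margin <= cy <= size - margin):
            continue
        too_close = any(
            np.hypot(cx - fx, cy - fy) < 0.6 * (r + fr) for fx, fy, fr, _ in fruits
        )
        if too_close:
            continue
        class_id = int(rng.choice(3, p=spec.class_mix))
        fruits.append((cx, cy, r, class_id))

    # --- draw fruits with multiplicative radial shading -------------------
    yy, xx = np.mgrid[0:size, 0:size]
    fruit_masks: list[np.ndarray] = []
    owner = np.full((size, size), -1, dtype=np.int64)  # topmost fruit per pixel
    for idx, (cx, cy, r, class_id) in enumerate(fruits):
        color = _sample_class_color(class_id, spec.illumination_gain, rng)
        rr, cc = skdraw.disk((cy, cx), r, shape=(size, size))
        mask = np.zeros((size, size), dtype=bool)
        mask[rr, cc] = True
        dist = np.hypot(xx[rr, cc] - cx, yy[rr, cc] - cy) / max(r, 1e-9)
        shade = 1.0 - (1.0 - _MIN_SHADING) * dist  # center bright, rim darker
        img[rr, cc] = np.clip(
            np.round(color[None, :] * shade[:, None] * spec.illumination_gain), 0, 255
        )
        fruit_masks.append(mask)
        owner[mask] = idx

    # --- leaf occluders with exact cap coverage ---------------------------
    occluder_mask = np.zeros((size, size), dtype=bool)
    for idx, (cx, cy, r, _) in enumerate(fruits):
        if rng.random() >= spec.occluder_density:
            continue
        frac = rng.uniform(0.15, 0.75)
        d = _cap_chord_offset(r, frac)
        theta = rng.uniform(0, 2 * np.pi)
        ux, uy = np.cos(theta), np.sin(theta)  # outward normal of the chord
        px, py = -uy, ux  # along the chord
        # minimal quadrilateral covering the cap beyond the chord: the
        # tight footprint keeps spillover onto clustered neighbors low,
        # so per-fruit coverage stays close to the drawn cap fraction
        half = np.sqrt(max(r**2 - d**2, 0.0)) + 1.0
        depth = (r - d) + 1.0
        bx, by = cx + d * ux, cy + d * uy
        quad = np.array(
            [
                [by - half * py, bx - half * px],
                [by + half * py, bx + half * px],
                [by + half * py + depth * uy, bx + half * px + depth * ux],
                [by - half * py + depth * uy, bx - half * px + depth * ux],
            ]
        )
        rr, cc = skdraw.polygon(quad[:, 0], quad[:, 1], shape=(size, size))
        leaf_color = _hsv_to_rgb255(rng.uniform(75, 115), rng.uniform(0.12, 0.30), rng.uniform(55, 110))
        img[rr, cc] = np.clip(leaf_color * spec.illumination_gain, 0, 255)
        occluder_mask[rr, cc] = True
        owner[rr, cc] = -2  # leaf on top

    # --- exact visible-area occlusion fractions ---------------------------
    boxes, occluded, classes = [], [], []
    for idx, (cx, cy, r, class_id) in enumerate(fruits):
        mask = fruit_masks[idx]
        total = int(mask.sum())
        visible = int((owner[mask] == idx).sum())
        occluded.append(1.0 - visible / max(total, 1))
        x1, y1 = max(cx - r, 0.0), max(cy - r, 0.0)
        x2, y2 = min(cx + r, float(size)), min(cy + r, float(size))
        boxes.append(
            BoxAnnotation(
                class_id,
                (x1 + x2) / 2 / size,
                (y1 + y2) / 2 / size,
                (x2 - x1) / size,
                (y2 - y1) / size,
            )
        )
        classes.append(class_id)

    truth = SceneTruth(boxes=boxes, occluded_fraction=occluded, classes=classes, occluder_mask=occluder_mask)
    return img.astype(np.uint8), truth


# ---------------------------------------------------------------------------
@dataclass(frozen=True)
class AugmentPolicy:
    """Augmentation ranges; defaults follow the study's printed policy."""

    hflip_prob: float = 0.5
    vflip_prob: float = 0.5
    rotation_deg: float = 15.0
    crop_min_fraction: float = 0.8  # random crop size as a fraction of the image
    crop_prob: float = 0.5
    brightness: float = 0.30
    contrast: float = 0.25
    hue_deg: float = 10.0
    saturation: float = 0.30
    min_box_area_px: float = 4.0

    @staticmethod
    def identity() -> "AugmentPolicy":
        return AugmentPolicy(
            hflip_prob=0.0,
            vflip_prob=0.0,
            rotation_deg=0.0,
            crop_prob=0.0,
            brightness=0.0,
            contrast=0.0,
            hue_deg=0.0,
            saturation=0.0,
        )


def _rotate_boxes(boxes, angle_deg, size):
    """Axis-aligned hull of each box's corners under rotation about center."""
    t = np.deg2rad(angle_deg)
    c, s = np.cos(t), np.sin(t)
    half = size / 2.0
    out = []
    for b in boxes:
        x1, y1, x2, y2 = b.to_xyxy(size, size)
        corners = np.array([[x1, y1], [x2, y1], [x2, y2], [x1, y2]]) - half
        # image rotation by +a moves content by rotation matrix R(-a) in
        # array coordinates; boxes follow the content
        rot = np.array([[c, s], [-s, c]])
        moved = corners @ rot.T + half
        out.append((b.class_id, moved[:, 0].min(), moved[:, 1].min(), moved[:, 0].max(), moved[:, 1].max()))
    return out


def _clip_and_pack(raw, size, min_area):
    boxes = []
    for class_id, x1, y1, x2, y2 in raw:
        x1, y1 = max(x1, 0.0), max(y1, 0.0)
        x2, y2 = min(x2, float(size)), min(y2, float(size))
        if x2 - x1 <= 0 or y2 - y1 <= 0 or (x2 - x1) * (y2 - y1) < min_area:
            continue
        boxes.append(
            BoxAnnotation(class_id, (x1 + x2) / 2 / size, (y1 + y2) / 2 / size, (x2 - x1) / size, (y2 - y1) / size)
        )
    return boxes


def augment(
    image: np.ndarray,
    boxes: list[BoxAnnotation],
    policy: AugmentPolicy = AugmentPolicy(),
    seed: int = 0,
) -> tuple[np.ndarray, list[BoxAnnotation]]:
    """Seeded geometric + photometric augmentation with consistent boxes."""
    rng = np.random.default_rng(seed)
    img = np.asarray(image, dtype=np.float64)
    size = img.shape[0]
    raw = [(b.class_id,) + b.to_xyxy(size, size) for b in boxes]

    if policy.hflip_prob > 0 and rng.random() < policy.hflip_prob:
        img = img[:, ::-1]
        raw = [(c, size - x2, y1, size - x1, y2) for c, x1, y1, x2, y2 in raw]
    if policy.vflip_prob > 0 and rng.random() < policy.vflip_prob:
        img = img[::-1]
        raw = [(c, x1, size - y2, x2, size - y1) for c, x1, y1, x2, y2 in raw]
    if policy.rotation_deg > 0:
        angle = rng.uniform(-policy.rotation_deg, policy.rotation_deg)
        img = sktransform.rotate(img / 255.0, angle, resize=False, mode="constant", cval=0.35) * 255.0
        packed = [BoxAnnotation(c, (x1 + x2) / 2 / size, (y1 + y2) / 2 / size, (x2 - x1) / size, (y2 - y1) / size) for c, x1, y1, x2, y2 in raw]
        raw = _rotate_boxes(packed, angle, size)
    if policy.crop_prob > 0 and rng.random() < policy.crop_prob:
        frac = rng.uniform(policy.crop_min_fraction, 1.0)
        cw = int(round(size * frac))
        ox = rng.integers(0, size - cw + 1)
        oy = rng.integers(0, size - cw + 1)
        img = sktransform.resize(img[oy : oy + cw, ox : ox + cw] / 255.0, (size, size), order=1, mode="reflect") * 255.0
        scale = size / cw
        raw = [(c, (x1 - ox) * scale, (y1 - oy) * scale, (x2 - ox) * scale, (y2 - oy) * scale) for c, x1, y1, x2, y2 in raw]

    # photometric transforms never touch the boxes
    if policy.brightness > 0:
        img = img * (1.0 + rng.uniform(-policy.brightness, policy.brightness))
    if policy.contrast > 0:
        mean = img.mean()
        img = (img - mean) * (1.0 + rng.uniform(-policy.contrast, policy.contrast)) + mean
    if policy.hue_deg > 0 or policy.saturation > 0:
        hsv = rgb2hsv(np.clip(img, 0, 255) / 255.0)
        if policy.hue_deg > 0:
            hsv[..., 0] = np.mod(hsv[..., 0] + rng.uniform(-policy.hue_deg, policy.hue_deg) / 360.0, 1.0)
        if policy.saturation > 0:
            hsv[..., 1] = np.clip(hsv[..., 1] * (1.0 + rng.uniform(-policy.saturation, policy.saturation)), 0, 1)
        img = hsv2rgb(hsv) * 255.0

    img = np.clip(np.round(img), 0, 255).astype(np.uint8)
    return img, _clip_and_pack(raw, size, policy.min_box_area_px)


# ---------------------------------------------------------------------------
def _split_sizes(n: int, fractions: tuple[float, float, float]) -> list[int]:
    """Largest-remainder apportionment; sizes sum to n, within +-1 of exact."""
    exact = [n * f for f in fractions]
    sizes = [int(np.floor(e)) for e in exact]
    rem = n - sum(sizes)
    order = np.argsort([s - e for s, e in zip(sizes, exact)])
    for i in range(rem):
        sizes[order[i]] += 1
    return sizes


def write_dataset(
    scenes: list[SceneSpec],
    out_dir: str | Path,
    split: tuple[float, float, float] = (0.70, 0.15, 0.15),
    density_params: DensityKernelParams | None = None,
) -> dict:
    """Render scenes to disk as PNG + YOLO labels + condition rasters.

    Layout: ``<out>/<split>/images/scene_<i>.png``, matching
    ``labels/scene_<i>.txt``, and ``conditions/scene_<i>.occlusion.npy``
    / ``.density.npy`` (float32).  Returns (and writes) a manifest
    listing every file per split.
    """
    if not scenes:
        raise ValueError("empty scene list")
    if abs(sum(split) - 1.0) > 1e-9:
        raise ValueError("split fractions must sum to 1")
    out_dir = Path(out_dir)
    sizes = _split_sizes(len(scenes), split)
    names = ["train", "val", "test"]
    manifest: dict = {"splits": {}}
    i = 0
    for split_name, count in zip(names, sizes):
        entries = []
        for _ in range(count):
            spec = scenes[i]
            stem = f"scene_{i:04d}"
            img, truth = render_scene(spec)
            img_dir = out_dir / split_name / "images"
            lbl_dir = out_dir / split_name / "labels"
            cond_dir = out_dir / split_name / "conditions"
            for d in (img_dir, lbl_dir, cond_dir):
                d.mkdir(parents=True, exist_ok=True)
            iio.imwrite(img_dir / f"{stem}.png", img)
            write_yolo_labels(lbl_dir / f"{stem}.txt", truth.boxes)
            occ = generate_occlusion_map(img).astype(np.float32)
            den = generate_density_map(
                truth.boxes, spec.image_size, spec.image_size, density_params
            ).astype(np.float32)
            np.save(cond_dir / f"{stem}.occlusion.npy", occ)
            np.save(cond_dir / f"{stem}.density.npy", den)
            entries.append(stem)
            i += 1
        manifest["splits"][split_name] = entries
    (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest
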