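"""Colorimetric maturity classification of coffee-cherry pixels.

Maturity is read from exocarp color with fixed HSV/RGB thresholds:

* **unripe** — dominant green: hue 60-120 deg, saturation 0.35-0.85,
  G > R and G > B;
* **semi-ripe** — transitional yellow-orange: hue 20-60 deg, with
  R close to G (|R - G| <= 20) or R slightly greater (0 < R - G <= 30);
* **ripe** — deep red: hue in [0, 20) or [340, 360), saturation > 0.6,
  R > G + 15 and R > B + 15.

Classes are evaluated in the order ripe -> semi-ripe -> unripe (the
ripe rule is the strictest compound condition), hue intervals are
half-open on the upper bound except the wrap-around ripe interval, and
pixels matching no rule are *unclassified*.  Hue/saturation follow the
standard hexagonal HSV conversion (hue on [0, 360), saturation =
delta / max).
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum

import numpy as np

from .boxes import BoxAnnotation

__all__ = [
    "MaturityClass",
    "ColorRuleSet",
    "DEFAULT_RULES",
    "classify_rgb_pixel",
    "classify_pixels",
    "classify_box",
]


class MaturityClass(Enum):
    UNRIPE = "unripe"
    SEMI_RIPE = "semi_ripe"
    RIPE = "ripe"
    UNCLASSIFIED = "unclassified"


# class ids used throughout the synthetic data and the detector
CLASS_IDS = {MaturityClass.UNRIPE: 0, MaturityClass.SEMI_RIPE: 1, MaturityClass.RIPE: 2}
CLASS_NAMES = {v: k for k, v in CLASS_IDS.items()}


@dataclass
class ColorRuleSet:
    """Threshold constants; defaults are the package's canonical rules."""

    unripe_hue: tuple[float, float] = (60.0, 120.0)
    unripe_sat: tuple[float, float] = (0.35, 0.85)
    semi_hue: tuple[float, float] = (20.0, 60.0)
    semi_rg_tolerance: float = 20.0  # |R - G| <= tol  ("R approximately G")
    semi_rg_margin: float = 30.0  # 0 < R - G <= margin  ("R slightly greater")
    ripe_hue_low: tuple[float, float] = (0.0, 20.0)
    ripe_hue_high: tuple[float, float] = (340.0, 360.0)
    ripe_sat_min: float = 0.6
    ripe_rgb_margin: float = 15.0  # R > G + m and R > B + m

    def __post_init__(self):
        for lo, hi in (self.unripe_hue, self.semi_hue, self.ripe_hue_low, self.ripe_hue_high):
            if lo > hi:
                raise ValueError("malformed hue interval")
        if self.semi_rg_tolerance < 0 or self.semi_rg_margin < 0 or self.ripe_rgb_margin < 0:
            raise ValueError("margins must be >= 0")


DEFAULT_RULES = ColorRuleSet()


def _hue_sat(r: np.ndarray, g: np.ndarray, b: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Hexagonal HSV hue [0, 360) and saturation delta/max from 8-bit RGB."""
    r, g, b = (np.asarray(c, dtype=np.float64) for c in (r, g, b))
    mx = np.maximum(np.maximum(r, g), b)
    mn = np.minimum(np.minimum(r, g), b)
    delta = mx - mn
    hue = np.zeros_like(mx)
    safe = delta > 0
    d = np.where(safe, delta, 1.0)
    hr = np.mod((g - b) / d, 6.0)
    hg = (b - r) / d + 2.0
    hb = (r - g) / d + 4.0
    hue = np.where(mx == r, hr, np.where(mx == g, hg, hb)) * 60.0
    hue = np.where(safe, np.mod(hue, 360.0), 0.0)
    sat = np.where(mx > 0, delta / np.where(mx > 0, mx, 1.0), 0.0)
    return hue, sat


def classify_pixels(rgb: np.ndarray, rules: ColorRuleSet = DEFAULT_RULES) -> np.ndarray:
    """Vectorized classification of an (..., 3) uint8 array.

    Returns an integer array: 0 unripe, 1 semi-ripe, 2 ripe,
    -1 unclassified.
    """
    rgb = np.asarray(rgb, dtype=np.float64)
    r, g, b = rgb[..., 0], rgb[..., 1], rgb[..., 2]
    hue, sat = _hue_sat(r, g, b)
    out = np.full(hue.shape, -1, dtype=np.int64)

    ripe = (
        (
            ((hue >= rules.ripe_hue_low[0]) & (hue < rules.ripe_hue_low[1]))
            | ((hue >= rules.ripe_hue_high[0]) & (hue <= rules.ripe_hue_high[1]))
        )
        & (sat > rules.ripe_sat_min)
        & (r > g + rules.ripe_rgb_margin)
        & (r > b + rules.ripe_rgb_margin)
    )
    semi = (
        (hue >= rules.semi_hue[0])
        & (hue < rules.semi_hue[1])
        & ((np.abs(r - g) <= rules.semi_rg_tolerance) | ((r - g > 0) & (r - g <= rules.semi_rg_margin)))
    )
    unripe = (
        (hue >= rules.unripe_hue[0])
        & (hue < rules.unripe_hue[1])
        & (sat >= rules.unripe_sat[0])
        & (sat <= rules.unripe_sat[1])
        & (g > r)
        & (g > b)
    )
    # precedence: ripe, then semi-ripe, then unripe
    out[unripe] = CLASS_IDS[MaturityClass.UNRIPE]
    out[semi] = CLASS_IDS[MaturityClass.SEMI_RIPE]
    out[ripe] = CLASS_IDS[MaturityClass.RIPE]
    return out


def classify_rgb_pixel(r: int, g: int, b: int, rules: ColorRuleSet = DEFAULT_RULES) -> MaturityClass:
    """Classify one 8-bit RGB pixel (pure function)."""
    for c in (r, g, b):
        if not 0 <= c <= 255:
            raise ValueError(f"channel value {c} outside 0-255")
    label = int(classify_pixels(np.array([[r, g, b]]), rules)[0])
    return CLASS_NAMES.get(label, MaturityClass.UNCLASSIFIED)


def classify_box(
    image: np.ndarray, box: BoxAnnotation, rules: ColorRuleSet = DEFAULT_RULES
) -> tuple[MaturityClass, float]:
    """Majority vote over classified pixels inside a normalized box.

    Returns the winning class and its share of classified pixels; a
    box with no classified pixels is (unclassified, 0.0).
    """
    image = np.asarray(image)
    h, w = image.shape[:2]
    x1, y1, x2, y2 = box.to_xyxy(w, h)
    xi1, yi1 = max(int(np.floor(x1)), 0), max(int(np.floor(y1)), 0)
    xi2, yi2 = min(int(np.ceil(x2)), w), min(int(np.ceil(y2)), h)
    if xi2 <= xi1 or yi2 <= yi1:
        raise ValueError(f"degenerate box after denormalization: {box}")
    labels = classify_pixels(image[yi1:yi2, xi1:xi2], rules).ravel()
    labels = labels[labels >= 0]
    if labels.size == 0:
        return MaturityClass.UNCLASSIFIED, 0.0
    counts = np.bincount(labels, minlength=3)
    winner = int(np.argmax(counts))
    return CLASS_NAMES[winner], float(counts[winner] / labels.size)
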