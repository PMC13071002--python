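"""Occlusion and density condition maps.

Two per-pixel rasters in [0, 1] act as auxiliary guidance for the
condition-guided attention block:

* the **density map** encodes fruit clustering intensity by summing one
  isotropic Gaussian per annotated fruit center, with a
  geometry-adaptive bandwidth: sigma_i = clamp(beta * dbar_i,
  sigma_min, sigma_max), where dbar_i is the mean center-to-center
  distance to the k nearest other fruits (the crowd-counting
  convention).  Tighter clusters therefore get sharper kernels.
* the **occlusion map** approximates canopy-induced visibility
  degradation from the image alone, combining local contrast
  attenuation (flat overpainted regions lose local variance relative
  to the scene) with an edge-discontinuity term from gradient
  magnitudes.

Both maps are produced at image resolution and area-pooled down to each
feature-map scale with :func:`pool_condition`.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from scipy.spatial import cKDTree

from .boxes import BoxAnnotation

__all__ = [
    "ConditionPair",
    "DensityKernelParams",
    "generate_density_map",
    "generate_occlusion_map",
    "pool_condition",
]

_EPS = 1e-6


@dataclass
class DensityKernelParams:
    """Adaptive-Gaussian bandwidth rule for the density map."""

    neighbor_count: int = 3
    scale_beta: float = 0.3
    sigma_min: float = 1.0
    sigma_max: float = 15.0

    def __post_init__(self):
        if self.neighbor_count < 1:
            raise ValueError("neighbor_count must be >= 1")
        if self.scale_beta <= 0 or self.sigma_min <= 0 or self.sigma_max <= 0:
            raise ValueError("beta and sigma bounds must be positive")
        if self.sigma_min > self.sigma_max:
            raise ValueError("sigma_min must not exceed sigma_max")


@dataclass
class ConditionPair:
    """Occlusion raster O and density raster D, each (1, H, W) in [0, 1]."""

    occlusion: np.ndarray
    density: np.ndarray

    def __post_init__(self):
        self.occlusion = np.asarray(self.occlusion, dtype=np.float64)
        self.density = np.asarray(self.density, dtype=np.float64)
        for name, r in (("occlusion", self.occlusion), ("density", self.density)):
            if r.ndim != 3 or r.shape[0] != 1:
                raise ValueError(f"{name} raster must have shape (1, H, W), got {r.shape}")
            if not np.all(np.isfinite(r)) or r.min() < 0 or r.max() > 1:
                raise ValueError(f"{name} raster values must be finite and in [0, 1]")
        if self.occlusion.shape != self.density.shape:
            raise ValueError("occlusion and density must share spatial dimensions")

    @property
    def source_resolution(self) -> tuple[int, int]:
        return self.occlusion.shape[1], self.occlusion.shape[2]

    def pooled(self, target_h: int, target_w: int) -> "ConditionPair":
        return ConditionPair(
            pool_condition(self.occlusion, target_h, target_w),
            pool_condition(self.density, target_h, target_w),
        )


def _adaptive_sigmas(centers: np.ndarray, params: DensityKernelParams) -> np.ndarray:
    n = len(centers)
    k = params.neighbor_count
    if n <= k:
        # not enough neighbors to estimate local spacing
        return np.full(n, params.sigma_min)
    tree = cKDTree(centers)
    # query k+1 because the nearest neighbor of a point is itself
    dists, _ = tree.query(centers, k=k + 1)
    dbar = dists[:, 1:].mean(axis=1)
    return np.clip(params.scale_beta * dbar, params.sigma_min, params.sigma_max)


def generate_density_map(
    boxes: list[BoxAnnotation],
    height: int,
    width: int,
    params: DensityKernelParams | None = None,
) -> np.ndarray:
    """Sum adaptive Gaussians at box centers; normalize into [0, 1).

    Each kernel integrates to ~1 before normalization (it is a discrete
    unit Gaussian evaluated at pixel centers).  The summed raster is
    divided by (max + 1e-6) so that values lie strictly below 1.
    An empty box list yields an all-zero raster.
    """
    if height < 1 or width < 1:
        raise ValueError("height and width must be >= 1")
    params = params or DensityKernelParams()
    out = np.zeros((height, width), dtype=np.float64)
    if not boxes:
        return out[None]
    for b in boxes:
        b.validate()
    centers = np.array([[b.cx * width, b.cy * height] for b in boxes])  # (x, y) px
    sigmas = _adaptive_sigmas(centers, params)
    for (cx, cy), sigma in zip(centers, sigmas):
        r = int(np.ceil(4 * sigma))
        # pixel centers at index + 0.5
        x0 = max(int(np.floor(cx - r)), 0)
        x1 = min(int(np.ceil(cx + r)) + 1, width)
        y0 = max(int(np.floor(cy - r)), 0)
        y1 = min(int(np.ceil(cy + r)) + 1, height)
        if x0 >= x1 or y0 >= y1:
            continue
        # kernels sampled at integer pixel indices so an exactly centered
        # box peaks at a single unambiguous pixel
        xs = np.arange(x0, x1, dtype=np.float64)
        ys = np.arange(y0, y1, dtype=np.float64)
        gx = np.exp(-((xs - cx) ** 2) / (2 * sigma**2))
        gy = np.exp(-((ys - cy) ** 2) / (2 * sigma**2))
        kernel = np.outer(gy, gx) / (2 * np.pi * sigma**2)
        out[y0:y1, x0:x1] += kernel
    m = out.max()
    if m > 0:
        out = out / (m + _EPS)
    return out[None]


def generate_occlusion_map(
    image: np.ndarray, window: int = 7, weight_contrast: float = 0.5
) -> np.ndarray:
    """Estimate per-pixel visibility degradation from an RGB image.

    ``O = clip(w * contrast_attenuation + (1 - w) * edge_discontinuity)``
    where the attenuation term is ``1 - s_local / (s_global + eps)``
    (grayscale standard deviation in a ``window x window`` box versus
    the whole image) and the edge term is the normalized Sobel gradient
    magnitude.  Both terms are ratios, so the map is invariant to
    global affine brightness changes up to the epsilon guard.  Images
    with near-zero global contrast return all zeros.
    """
    image = np.asarray(image)
    if image.ndim != 3 or image.shape[2] != 3:
        raise ValueError(f"expected an (H, W, 3) RGB image, got shape {image.shape}")
    gray = image.astype(np.float64) @ np.array([0.299, 0.587, 0.114])
    s_global = gray.std()
    if s_global < _EPS:
        return np.zeros((1,) + gray.shape)
    # local std via the moments trick with a box filter
    mu = ndimage.uniform_filter(gray, size=window, mode="reflect")
    mu2 = ndimage.uniform_filter(gray * gray, size=window, mode="reflect")
    s_local = np.sqrt(np.clip(mu2 - mu * mu, 0.0, None))
    attenuation = np.clip(1.0 - s_local / (s_global + _EPS), 0.0, 1.0)
    gx = ndimage.sobel(gray, axis=1, mode="reflect")
    gy = ndimage.sobel(gray, axis=0, mode="reflect")
    gmag = np.hypot(gx, gy)
    edges = gmag / (gmag.max() + _EPS)
    out = weight_contrast * attenuation + (1.0 - weight_contrast) * edges
    return np.clip(out, 0.0, 1.0)[None]


def pool_condition(raster: np.ndarray, target_h: int, target_w: int) -> np.ndarray:
    """Area-average pooling of a (..., H, W) raster to (target_h, target_w).

    Each source pixel contributes to exactly one target cell (assignment
    by ``floor(i * target / source)``), so every output value is a mean
    of source values and stays within the input's [min, max] range.
    """
    raster = np.asarray(raster, dtype=np.float64)
    h, w = raster.shape[-2:]
    if target_h < 1 or target_w < 1:
        raise ValueError("target dimensions must be >= 1")
    if target_h > h or target_w > w:
        raise ValueError(f"target ({target_h}, {target_w}) exceeds source ({h}, {w})")
    if (target_h, target_w) == (h, w):
        return raster.copy()
    row_bin = (np.arange(h) * target_h) // h
    col_bin = (np.arange(w) * target_w) // w
    lead = raster.shape[:-2]
    flat = raster.reshape(-1, h, w)
    out = np.zeros((flat.shape[0], target_h, target_w))
    counts = np.zeros((target_h, target_w))
    np.add.at(counts, (row_bin[:, None], col_bin[None, :]), 1.0)
    for i in range(flat.shape[0]):
        acc = np.zeros((target_h, target_w))
        np.add.at(acc, (row_bin[:, None], col_bin[None, :]), flat[i])
        out[i] = acc / counts
    return out.reshape(lead + (target_h, target_w))
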