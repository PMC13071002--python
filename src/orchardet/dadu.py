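"""Dual-Adaptive Dynamic Upsampling (DADU).

Content-adaptive x``s`` upsampling by sampling the input feature grid
at displaced positions.  Two branches predict sampling offsets with
complementary receptive fields — a 1x1 pointwise convolution (global,
content-uniform trends) and a 3x3 convolution (local, boundary-aware
adjustments) — fused by a learnable sigmoid-weighted convex
combination:

    delta_fused = sigmoid(alpha) * delta_1 + (1 - sigmoid(alpha)) * delta_2

Each output cell of each of G channel groups is then bilinearly
interpolated at ``P_base + delta_fused``, with border replication for
out-of-range positions.  Offsets are predicted in units of source-grid
cells and converted to the [-1, 1] normalized coordinates of the
sampler (align-corners-false cell-center convention).  Optional
extras: a pixel-shuffle pre-expansion ("PL" mode, channels / s^2), and
a dynamic scope that contracts offset magnitudes through a learned
per-position factor in (0, 1).

Offset convolutions are zero-initialized: a fresh block reduces to
plain base-grid (bilinear-style) resampling and is independent of the
fusion weight.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import nn
from .nn import Tensor
from .nn import functional as F

__all__ = ["DADUConfig", "DADU", "fuse_offsets", "make_base_grid"]


@dataclass
class DADUConfig:
    channels: int
    scale: int = 2
    groups: int = 4
    mode: str = "direct"  # {"direct", "PL"}
    dynamic_scope: bool = False
    fusion_param_init: float = 0.5

    def __post_init__(self):
        if self.scale < 1:
            raise ValueError("scale must be >= 1")
        if self.mode not in ("direct", "PL"):
            raise ValueError(f"mode must be 'direct' or 'PL', got {self.mode!r}")
        c = self.channels if self.mode == "direct" else None
        if self.mode == "PL":
            if self.channels % (self.scale**2):
                raise ValueError("PL mode requires channels divisible by scale^2")
            c = self.channels // (self.scale**2)
        if c % self.groups:
            raise ValueError(f"effective channels {c} not divisible by groups {self.groups}")


def fuse_offsets(d1: Tensor, d2: Tensor, fusion_param) -> Tensor:
    """Convex combination sigmoid(p) * d1 + (1 - sigmoid(p)) * d2."""
    if d1.shape != d2.shape:
        raise ValueError(f"offset shape mismatch: {d1.shape} vs {d2.shape}")
    p = fusion_param if isinstance(fusion_param, Tensor) else Tensor(float(fusion_param))
    w = p.sigmoid()
    return d1 * w + d2 * (1.0 - w)


def make_base_grid(h_in: int, w_in: int, s: int) -> tuple[np.ndarray, np.ndarray]:
    """Continuous source pixel coords of each (s*H, s*W) output cell.

    Cell-center convention (align-corners false): output cell (i, j)
    maps to source coordinate ((j + 0.5) / s - 0.5, (i + 0.5) / s - 0.5),
    which preserves the mean position at any scale.
    """
    ys = (np.arange(s * h_in) + 0.5) / s - 0.5
    xs = (np.arange(s * w_in) + 0.5) / s - 0.5
    gy, gx = np.meshgrid(ys, xs, indexing="ij")
    return gx, gy


class _OffsetBranch(nn.Module):
    """Zero-initialized conv predicting (2 * G * s^2) offset channels."""

    def __init__(self, channels: int, groups: int, s: int, kernel: int):
        super().__init__()
        self.conv = nn.Conv2d(channels, 2 * groups * s * s, kernel, padding=kernel // 2, zero_init=True)

    def forward(self, x: Tensor) -> Tensor:
        return self.conv(x)


class DADU(nn.Module):
    def __init__(self, config: DADUConfig, rng: np.random.Generator | None = None):
        super().__init__()
        self.config = config
        c = config.channels if config.mode == "direct" else config.channels // config.scale**2
        s = 1 if config.mode == "PL" else config.scale  # PL pre-expands space
        self.effective_channels = c
        self.offset_subpixels = s
        self.branch1 = _OffsetBranch(c, config.groups, s, kernel=1)
        self.branch2 = _OffsetBranch(c, config.groups, s, kernel=3)
        self.fusion_param = nn.Parameter(np.array(config.fusion_param_init))
        if config.dynamic_scope:
            self.scope_conv = nn.Conv2d(c, 2 * config.groups * s * s, 1, zero_init=True)
        else:
            self.scope_conv = None

    # ------------------------------------------------------------------
    def predict_offsets(self, x: Tensor, branch: str) -> Tensor:
        if branch == "pointwise":
            return self.branch1(x)
        if branch == "spatial":
            return self.branch2(x)
        raise ValueError(f"unknown branch {branch!r}")

    def apply_scope(self, offsets: Tensor, x: Tensor) -> Tensor:
        """Contract offsets by a learned per-position factor in (0, 1)."""
        if self.scope_conv is None:
            raise ValueError("dynamic_scope is not enabled in the config")
        return offsets * self.scope_conv(x).sigmoid()

    def _sample(self, x: Tensor, offsets: Tensor, s: int) -> Tensor:
        """Group-wise bilinear sampling at base grid + offsets.

        ``x``: (B, C, H, W); ``offsets``: (B, 2*G*s^2, H, W) in source
        cell units.  Output: (B, C, s*H, s*W), groups concatenated
        along channels.
        """
        b, c, h, w = x.shape
        g = self.config.groups
        gx, gy = make_base_grid(h, w, s)
        # (B, 2, G, s, s, H, W) -> spread sub-pixel offsets onto the output grid
        off = offsets.reshape(b, 2, g, s, s, h, w).transpose(0, 1, 2, 5, 3, 6, 4)
        off = off.reshape(b, 2, g, s * h, s * w)
        outs = []
        cg = c // g
        for gi in range(g):
            ox = off[:, 0, gi]  # (B, sH, sW), in source-cell units
            oy = off[:, 1, gi]
            px = (Tensor(gx[None]) + ox + 0.5) * (2.0 / w) - 1.0
            py = (Tensor(gy[None]) + oy + 0.5) * (2.0 / h) - 1.0
            outs.append(F.grid_sample(x[:, gi * cg : (gi + 1) * cg], px, py))
        return nn.concatenate(outs, axis=1)

    def forward(self, x: Tensor) -> Tensor:
        cfg = self.config
        if x.shape[1] != cfg.channels:
            raise ValueError(f"input has {x.shape[1]} channels, config expects {cfg.channels}")
        if cfg.mode == "PL":
            x = F.pixel_shuffle(x, cfg.scale)
            s = 1
        else:
            s = cfg.scale
        d1 = self.branch1(x)
        d2 = self.branch2(x)
        fused = fuse_offsets(d1, d2, self.fusion_param)
        if self.scope_conv is not None:
            fused = self.apply_scope(fused, x)
        return self._sample(x, fused, s)
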