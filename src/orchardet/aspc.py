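"""Attention-guided Space-Preserving Convolution (ASPC).

A downsample-by-two stage that keeps every input value.  Instead of a
strided convolution (which evaluates only a quarter of the spatial
positions), the block first applies a bijective space-to-depth
rearrangement — (B, C, H, W) -> (B, 4C, H/2, W/2), each 2x2 block
becoming four channel groups ordered (TL, TR, BL, BR) — then a 3x3
convolution, then cascaded attention gates:

    F_out = M_ch * (M_sp * Conv3x3(SPD(F_in)))
    M_sp  = sigmoid(Conv7x7([AvgPool_c(F); MaxPool_c(F)]))
    M_ch  = sigmoid(MLP(AvgPool(F)) + MLP(MaxPool(F)))

with the spatial gate applied first and the channel gate second, and a
shared bottleneck MLP (reduction ratio r) for the channel gate.  Both
gates are strictly inside (0, 1), so the gated output can never exceed
the convolution output in magnitude.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import nn
from .nn import Tensor
from .nn import functional as F

__all__ = ["ASPCConfig", "ASPC", "SpatialAttention", "ChannelAttention", "spd_transform", "spd_inverse"]


@dataclass
class ASPCConfig:
    in_channels: int
    out_channels: int
    spatial_kernel: int = 7
    channel_reduction: int = 16

    def __post_init__(self):
        if self.out_channels < 1:
            raise ValueError("out_channels must be >= 1")
        if self.channel_reduction < 1:
            raise ValueError("channel_reduction must be >= 1")
        if 4 * self.in_channels < self.channel_reduction:
            raise ValueError("channel_reduction exceeds 4 * in_channels")


def spd_transform(x: Tensor) -> Tensor:
    """Space-to-depth: (B, C, H, W) -> (B, 4C, ceil(H/2), ceil(W/2)).

    Odd spatial dims are zero-padded on the right/bottom first so the
    rearrangement stays bijective on the padded grid.
    """
    b, c, h, w = x.shape
    if h % 2 or w % 2:
        x = x.pad2d((0, h % 2), (0, w % 2))
    return F.space_to_depth(x)


def spd_inverse(x: Tensor) -> Tensor:
    """Depth-to-space inverse of :func:`spd_transform` (padded grid)."""
    return F.depth_to_space(x)


class SpatialAttention(nn.Module):
    """Eq-style position gate from channel-mean and channel-max planes."""

    def __init__(self, kernel: int = 7, rng: np.random.Generator | None = None):
        super().__init__()
        # zero-init: the gate starts neutral at 0.5 everywhere instead of
        # saturating on the spatially smooth mean/max planes
        self.conv = nn.Conv2d(2, 1, kernel, padding=kernel // 2, zero_init=True)

    def forward(self, x: Tensor) -> Tensor:
        avg = x.mean(axis=1, keepdims=True)
        mx = x.max(axis=1, keepdims=True)
        return self.conv(nn.concatenate([avg, mx], axis=1)).sigmoid()


class ChannelAttention(nn.Module):
    """Shared-bottleneck channel gate from global avg and max descriptors."""

    def __init__(self, channels: int, reduction: int = 16, rng: np.random.Generator | None = None):
        super().__init__()
        hidden = max(channels // reduction, 1)
        self.fc1 = nn.Linear(channels, hidden, rng=rng)
        self.fc2 = nn.Linear(hidden, channels, zero_init=True)  # neutral 0.5 gate at init

    def _mlp(self, desc: Tensor) -> Tensor:
        return self.fc2(self.fc1(desc).relu())

    def forward(self, x: Tensor) -> Tensor:
        b, c = x.shape[0], x.shape[1]
        avg = F.global_avg_pool(x).reshape(b, c)
        mx = F.global_max_pool(x).reshape(b, c)
        w = (self._mlp(avg) + self._mlp(mx)).sigmoid()
        return w.reshape(b, c, 1, 1)


class ASPC(nn.Module):
    def __init__(self, config: ASPCConfig, rng: np.random.Generator | None = None):
        super().__init__()
        rng = rng if rng is not None else np.random.default_rng(0)
        self.config = config
        self.conv = nn.Conv2d(4 * config.in_channels, config.out_channels, 3, padding=1, rng=rng)
        # each attention gate multiplies by ~0.5 at init; a gain of 4
        # keeps feature magnitudes stable through stacked ASPC stages
        self.conv.weight.data *= 4.0
        self.spatial = SpatialAttention(config.spatial_kernel, rng=rng)
        self.channel = ChannelAttention(config.out_channels, config.channel_reduction, rng=rng)

    def forward(self, x: Tensor) -> Tensor:
        if x.shape[1] != self.config.in_channels:
            raise ValueError(
                f"input has {x.shape[1]} channels, config expects {self.config.in_channels}"
            )
        y = self.conv(spd_transform(x))
        y = y * self.spatial(y)  # spatial gate first, per the composition rule
        y = y * self.channel(y)
        return y
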