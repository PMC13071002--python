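"""Condition-Guided Windowed Attention (CGWA).

Multi-head self-attention inside non-overlapping ``Ws x Ws`` windows
with a learned relative position bias, where the attention logits are
additionally conditioned on two per-pixel guidance rasters — an
occlusion map O and a density map D:

    A_enh = softmax(alpha(O, D) * (Q K^T / sqrt(d_k)) + B + beta(O, D)) V

* ``alpha``: per-window, head-specific multiplicative modulation in
  (0, 1), predicted by a two-layer MLP from the window's mean occlusion
  and density scores.  Windows with heavy occlusion or clustering get
  their logit temperature adjusted.
* ``B``: relative position bias, a (2 Ws - 1)^2-entry table indexed by
  the displacement between query and key positions.
* ``beta``: boundary weights in (0, 1) from a two-layer convolution
  over [O; D], added per key position so that condition boundaries
  attract attention.

Windowing keeps the score tensor at O(Ws^4 * (H/Ws) * (W/Ws)) entries
instead of O((HW)^2).  The output projection is zero-initialized, so a
freshly constructed block is exactly the identity (residual path only).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import nn
from .condition_maps import ConditionPair
from .nn import Tensor
from .nn import functional as F

__all__ = [
    "CGWAConfig",
    "WindowStats",
    "CGWA",
    "partition_windows",
    "merge_windows",
    "relative_position_index",
    "window_condition_stats",
]

_NEG_INF = -1e9


@dataclass
class CGWAConfig:
    channels: int
    heads: int = 4
    window_size: int = 7
    mlp_hidden: int = 16
    dropout_rate: float = 0.0
    refine_conditions: bool = True

    def __post_init__(self):
        if self.channels % self.heads:
            raise ValueError(f"channels={self.channels} not divisible by heads={self.heads}")
        if self.window_size < 1:
            raise ValueError("window_size must be >= 1")


@dataclass(frozen=True)
class WindowStats:
    mean_occlusion: float
    mean_density: float


# ---------------------------------------------------------------------------
def _pad_amounts(h: int, w: int, ws: int) -> tuple[int, int]:
    return (-h) % ws, (-w) % ws


def partition_windows(x: Tensor, ws: int) -> tuple[Tensor, np.ndarray, tuple[int, int]]:
    """Tile (B, C, H, W) into (B * nWin, Ws^2, C) windows.

    Returns the window tensor, a boolean validity mask (B * nWin, Ws^2)
    that is False on zero-padded cells, and the padded spatial shape.
    """
    b, c, h, w = x.shape
    ph, pw = _pad_amounts(h, w, ws)
    xp = x.pad2d((0, ph), (0, pw)) if (ph or pw) else x
    hp, wp = h + ph, w + pw
    nh, nw = hp // ws, wp // ws
    win = (
        xp.reshape(b, c, nh, ws, nw, ws)
        .transpose(0, 2, 4, 3, 5, 1)
        .reshape(b * nh * nw, ws * ws, c)
    )
    valid = np.zeros((hp, wp), dtype=bool)
    valid[:h, :w] = True
    mask = (
        valid.reshape(nh, ws, nw, ws)
        .transpose(0, 2, 1, 3)
        .reshape(nh * nw, ws * ws)
    )
    mask = np.tile(mask, (b, 1))
    return win, mask, (hp, wp)


def merge_windows(win: Tensor, b: int, c: int, h: int, w: int, ws: int) -> Tensor:
    """Inverse of :func:`partition_windows`, cropped back to (H, W)."""
    ph, pw = _pad_amounts(h, w, ws)
    hp, wp = h + ph, w + pw
    nh, nw = hp // ws, wp // ws
    x = (
        win.reshape(b, nh, nw, ws, ws, c)
        .transpose(0, 5, 1, 3, 2, 4)
        .reshape(b, c, hp, wp)
    )
    if ph or pw:
        x = x[:, :, :h, :w]
    return x


def relative_position_index(ws: int) -> np.ndarray:
    """(Ws^2, Ws^2) index into the (2Ws-1)^2-entry bias table.

    index[i][j] depends only on the (dy, dx) displacement between
    positions i and j, giving translation-equivariant bias lookups.
    """
    coords = np.stack(np.meshgrid(np.arange(ws), np.arange(ws), indexing="ij"), axis=-1)
    coords = coords.reshape(-1, 2)  # (Ws^2, [y, x])
    rel = coords[:, None, :] - coords[None, :, :] + (ws - 1)
    return rel[..., 0] * (2 * ws - 1) + rel[..., 1]


def window_condition_stats(
    occlusion: np.ndarray, density: np.ndarray, ws: int
) -> list[WindowStats]:
    """Mean occlusion/density per window, in row-major window order.

    Inputs are (1, H, W) rasters at the feature grid's resolution.
    Padded cells (when Ws does not divide H or W) are excluded from the
    means, so each mean stays within the window's [min, max].
    """
    occlusion = np.asarray(occlusion, dtype=np.float64)
    density = np.asarray(density, dtype=np.float64)
    if occlusion.shape != density.shape:
        raise ValueError(
            f"occlusion {occlusion.shape} and density {density.shape} resolution mismatch"
        )
    o2, d2 = occlusion.reshape(occlusion.shape[-2:]), density.reshape(density.shape[-2:])
    h, w = o2.shape
    ph, pw = _pad_amounts(h, w, ws)
    stats = []
    for top in range(0, h + ph, ws):
        for left in range(0, w + pw, ws):
            so = o2[top : top + ws, left : left + ws]
            sd = d2[top : top + ws, left : left + ws]
            stats.append(WindowStats(float(so.mean()), float(sd.mean())))
    return stats


class _ConditionEncoder(nn.Module):
    """Lightweight three-layer convolutional refiner for one raster."""

    def __init__(self, rng: np.random.Generator):
        super().__init__()
        self.net = nn.Sequential(
            nn.Conv2d(1, 8, 3, padding=1, rng=rng),
            nn.ReLU(),
            nn.Conv2d(8, 16, 3, padding=1, rng=rng),
            nn.ReLU(),
            nn.Conv2d(16, 1, 3, padding=1, rng=rng),
            nn.Sigmoid(),
        )

    def forward(self, x: Tensor) -> Tensor:
        return self.net(x)


class _BoundaryNet(nn.Module):
    """Two-layer conv over [O; D] -> single-channel weights in (0, 1)."""

    def __init__(self, rng: np.random.Generator, hidden: int = 8):
        super().__init__()
        self.net = nn.Sequential(
            nn.Conv2d(2, hidden, 3, padding=1, rng=rng),
            nn.ReLU(),
            nn.Conv2d(hidden, 1, 3, padding=1, rng=rng),
            nn.Sigmoid(),
        )

    def forward(self, od: Tensor) -> Tensor:
        return self.net(od)


class _ModulationMLP(nn.Module):
    """(mean O, mean D) -> head-specific factors strictly in (0, 1)."""

    def __init__(self, heads: int, hidden: int, dropout: float, rng: np.random.Generator):
        super().__init__()
        self.fc1 = nn.Linear(2, hidden, rng=rng)
        self.fc2 = nn.Linear(hidden, heads, rng=rng)
        self.dropout = dropout
        self._rng = rng

    def forward(self, stats: Tensor, training: bool) -> Tensor:
        h = self.fc1(stats).relu()
        h = F.dropout(h, self.dropout, self._rng, training)
        return self.fc2(h).sigmoid()


class CGWA(nn.Module):
    """The full condition-guided windowed attention block."""

    def __init__(self, config: CGWAConfig, rng: np.random.Generator | None = None):
        super().__init__()
        rng = rng if rng is not None else np.random.default_rng(0)
        self.config = config
        c, ws = config.channels, config.window_size
        self.qkv = nn.Linear(c, 3 * c, rng=rng)
        # zero-init output projection: the block is the identity at init
        self.proj = nn.Linear(c, c, zero_init=True)
        self.bias_table = nn.Parameter(np.zeros(((2 * ws - 1) ** 2, config.heads)))
        self.bias_index = relative_position_index(ws)
        self.modulation = _ModulationMLP(config.heads, config.mlp_hidden, config.dropout_rate, rng)
        self.boundary_net = _BoundaryNet(rng)
        self.occlusion_encoder = _ConditionEncoder(rng)
        self.density_encoder = _ConditionEncoder(rng)
        # test hook: freeze the modulation function at a constant
        self.frozen_modulation: float | None = None
        self.last_scores_entries: int | None = None

    # ------------------------------------------------------------------
    def relative_position_bias(self) -> Tensor:
        """(heads, Ws^2, Ws^2) bias gathered from the table."""
        flat = self.bias_index.reshape(-1)
        gathered = self.bias_table[flat]  # (Ws^4, heads)
        n = self.bias_index.shape[0]
        return gathered.reshape(n, n, self.config.heads).transpose(2, 0, 1)

    def _conditions_to_batch(self, conditions, b: int, h: int, w: int):
        if isinstance(conditions, ConditionPair):
            o, d = conditions.occlusion, conditions.density
        else:
            o, d = conditions
        o = np.asarray(o, dtype=np.float64)
        d = np.asarray(d, dtype=np.float64)
        if o.ndim == 3:
            o, d = o[None], d[None]
        if o.shape[0] == 1 and b > 1:
            o = np.broadcast_to(o, (b,) + o.shape[1:]).copy()
            d = np.broadcast_to(d, (b,) + d.shape[1:]).copy()
        if o.shape[-2:] != (h, w) or d.shape[-2:] != (h, w):
            raise ValueError(
                f"conditions at {o.shape[-2:]} do not match feature resolution {(h, w)}; "
                "pool them with pool_condition first"
            )
        return o, d

    def forward(self, x: Tensor, conditions) -> Tensor:
        cfg = self.config
        b, c, h, w = x.shape
        if c != cfg.channels:
            raise ValueError(f"input has {c} channels, config expects {cfg.channels}")
        ws = cfg.window_size
        n = ws * ws
        o_np, d_np = self._conditions_to_batch(conditions, b, h, w)
        o_t, d_t = Tensor(o_np), Tensor(d_np)
        if cfg.refine_conditions:
            o_t = self.occlusion_encoder(o_t)
            d_t = self.density_encoder(d_t)

        win, mask, _ = partition_windows(x, ws)  # (nWtot, N, C)
        nwtot = win.shape[0]
        qkv = self.qkv(win)  # (nWtot, N, 3C)
        dk = c // cfg.heads
        qkv = qkv.reshape(nwtot, n, 3, cfg.heads, dk).transpose(2, 0, 3, 1, 4)
        q, k, v = qkv[0], qkv[1], qkv[2]  # (nWtot, heads, N, dk)
        scores = (q @ k.transpose(0, 1, 3, 2)) * (1.0 / np.sqrt(dk))
        self.last_scores_entries = int(np.prod(scores.shape))

        # alpha(O, D): per-window head-specific modulation of the scaled logits
        if self.frozen_modulation is not None:
            factors = Tensor(np.full((nwtot, cfg.heads), float(self.frozen_modulation)))
        else:
            # window means over valid cells, differentiable through the encoders
            ow, _, _ = partition_windows(o_t, ws)
            dw, _, _ = partition_windows(d_t, ws)
            mask_t = Tensor(mask[..., None].astype(np.float64))
            denom = mask.sum(axis=1, keepdims=True).astype(np.float64)
            mo_t = (ow * mask_t).sum(axis=1) * Tensor(1.0 / denom)
            md_t = (dw * mask_t).sum(axis=1) * Tensor(1.0 / denom)
            stats = nn.concatenate([mo_t, md_t], axis=1)  # (nWtot, 2)
            factors = self.modulation(stats, self.training)  # (nWtot, heads)
        logits = scores * factors.reshape(nwtot, cfg.heads, 1, 1)

        logits = logits + self.relative_position_bias().reshape(1, cfg.heads, n, n)

        # beta(O, D): boundary weights added per key position
        beta = self.boundary_net(nn.concatenate([o_t, d_t], axis=1))  # (B, 1, H, W)
        beta_w, _, _ = partition_windows(beta, ws)  # (nWtot, N, 1)
        logits = logits + beta_w.reshape(nwtot, 1, 1, n)

        # padded cells receive -inf key logits -> zero attention mass
        key_mask = np.where(mask, 0.0, _NEG_INF)[:, None, None, :]
        logits = logits + Tensor(key_mask)
        attn = logits.softmax(axis=-1)
        out = attn @ v  # (nWtot, heads, N, dk)
        out = out.transpose(0, 2, 1, 3).reshape(nwtot, n, c)
        out = self.proj(out)
        merged = merge_windows(out, b, c, h, w, ws)
        return x + merged
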