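"""Differentiable array operations shared by the detection blocks.

``conv2d`` and ``grid_sample`` are primitives with hand-written
backward passes (im2col / scatter-add); everything else is composed
from the :class:`~orchardet.nn.tensor.Tensor` ops and inherits its
gradients for free.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import as_strided

from .tensor import MAC_COUNTER, Tensor

__all__ = [
    "conv2d",
    "grid_sample",
    "pixel_shuffle",
    "pixel_unshuffle",
    "space_to_depth",
    "depth_to_space",
    "dropout",
    "global_avg_pool",
    "global_max_pool",
]


def _im2col(xp: np.ndarray, kh: int, kw: int, stride: int):
    """View the padded input as (B, C, KH, KW, OH, OW) patches."""
    b, c, h, w = xp.shape
    oh = (h - kh) // stride + 1
    ow = (w - kw) // stride + 1
    sb, sc, sh, sw = xp.strides
    shape = (b, c, kh, kw, oh, ow)
    strides = (sb, sc, sh, sw, sh * stride, sw * stride)
    return as_strided(xp, shape=shape, strides=strides), oh, ow


def conv2d(
    x: Tensor,
    weight: Tensor,
    bias: Tensor | None = None,
    stride: int = 1,
    padding: int = 0,
) -> Tensor:
    """2-D cross-correlation, NCHW layout, weight (O, C, KH, KW)."""
    b, c, h, w = x.shape
    o, cw, kh, kw = weight.shape
    if cw != c:
        raise ValueError(f"conv2d: input has {c} channels, weight expects {cw}")
    xp = np.pad(x.data, ((0, 0), (0, 0), (padding, padding), (padding, padding)))
    patches, oh, ow = _im2col(xp, kh, kw, stride)
    cols = patches.reshape(b, c * kh * kw, oh * ow)  # copies the view
    wmat = weight.data.reshape(o, c * kh * kw)
    out_data = np.matmul(wmat, cols).reshape(b, o, oh, ow)
    if MAC_COUNTER["enabled"]:
        MAC_COUNTER["macs"] += b * o * oh * ow * c * kh * kw
    if bias is not None:
        out_data = out_data + bias.data.reshape(1, o, 1, 1)
    prev = (x, weight) + ((bias,) if bias is not None else ())
    out = Tensor(out_data, _prev=prev)

    def _bw(g):
        g2 = g.reshape(b, o, oh * ow)
        if weight.requires_grad:
            dw = np.einsum("bop,bkp->ok", g2, cols)
            weight._accumulate(dw.reshape(weight.shape))
        if bias is not None and bias.requires_grad:
            bias._accumulate(g.sum(axis=(0, 2, 3)))
        if x.requires_grad:
            dcols = np.matmul(wmat.T, g2)  # (B, C*KH*KW, OH*OW)
            dpatch = dcols.reshape(b, c, kh, kw, oh, ow)
            dxp = np.zeros_like(xp)
            for i in range(kh):
                for j in range(kw):
                    dxp[:, :, i : i + stride * oh : stride, j : j + stride * ow : stride] += dpatch[:, :, i, j]
            if padding:
                dxp = dxp[:, :, padding : padding + h, padding : padding + w]
            x._accumulate(dxp)

    out._backward = _bw
    return out


def grid_sample(x: Tensor, px: Tensor, py: Tensor) -> Tensor:
    """Bilinear sampling of ``x`` (B, C, H, W) at normalized positions.

    ``px``/``py`` have shape (B, OH, OW) with values in [-1, 1]
    (align-corners-false cell-center convention); out-of-range
    positions are handled by border replication.  Differentiable in
    ``x`` and in the positions.
    """
    b, c, h, w = x.shape
    _, oh, ow = px.shape
    # normalized -> continuous pixel coordinates
    ix = (px.data + 1.0) * 0.5 * w - 0.5
    iy = (py.data + 1.0) * 0.5 * h - 0.5
    # border mode: clamp the coordinate itself, then interpolate
    inx = (ix > 0.0) & (ix < w - 1.0)  # where the coord gradient survives
    iny = (iy > 0.0) & (iy < h - 1.0)
    ixc = np.clip(ix, 0.0, w - 1.0)
    iyc = np.clip(iy, 0.0, h - 1.0)
    x0 = np.floor(ixc).astype(np.int64)
    y0 = np.floor(iyc).astype(np.int64)
    x0 = np.minimum(x0, w - 2) if w > 1 else x0 * 0
    y0 = np.minimum(y0, h - 2) if h > 1 else y0 * 0
    x1 = np.minimum(x0 + 1, w - 1)
    y1 = np.minimum(y0 + 1, h - 1)
    fx = ixc - x0  # in [0, 1]
    fy = iyc - y0

    bi = np.arange(b)[:, None, None]
    v00 = x.data[bi, :, y0, x0]  # (B, OH, OW, C)
    v01 = x.data[bi, :, y0, x1]
    v10 = x.data[bi, :, y1, x0]
    v11 = x.data[bi, :, y1, x1]
    fxe = fx[..., None]
    fye = fy[..., None]
    val = (
        v00 * (1 - fxe) * (1 - fye)
        + v01 * fxe * (1 - fye)
        + v10 * (1 - fxe) * fye
        + v11 * fxe * fye
    )
    out = Tensor(np.moveaxis(val, -1, 1), _prev=(x, px, py))

    def _bw(g):
        gv = np.moveaxis(g, 1, -1)  # (B, OH, OW, C)
        if x.requires_grad:
            dx = np.zeros_like(x.data)
            # advanced indices separated by a slice put (B, OH, OW) first
            np.add.at(dx, (bi, slice(None), y0, x0), gv * (1 - fxe) * (1 - fye))
            np.add.at(dx, (bi, slice(None), y0, x1), gv * fxe * (1 - fye))
            np.add.at(dx, (bi, slice(None), y1, x0), gv * (1 - fxe) * fye)
            np.add.at(dx, (bi, slice(None), y1, x1), gv * fxe * fye)
            x._accumulate(dx)
        if px.requires_grad or py.requires_grad:
            dval_dix = (gv * ((v01 - v00) * (1 - fye) + (v11 - v10) * fye)).sum(axis=-1)
            dval_diy = (gv * ((v10 - v00) * (1 - fxe) + (v11 - v01) * fxe)).sum(axis=-1)
            if px.requires_grad:
                px._accumulate(dval_dix * inx * (0.5 * w))
            if py.requires_grad:
                py._accumulate(dval_diy * iny * (0.5 * h))

    out._backward = _bw
    return out


def space_to_depth(x: Tensor) -> Tensor:
    """2x2 spatial blocks -> 4 channel groups ordered (TL, TR, BL, BR).

    (B, C, H, W) -> (B, 4C, H/2, W/2); H and W must be even.
    """
    b, c, h, w = x.shape
    if h % 2 or w % 2:
        raise ValueError("space_to_depth requires even spatial dims")
    # (B, C, H/2, 2, W/2, 2) -> (B, 2, 2, C, H/2, W/2): index (dy, dx) leads
    y = x.reshape(b, c, h // 2, 2, w // 2, 2).transpose(0, 3, 5, 1, 2, 4)
    return y.reshape(b, 4 * c, h // 2, w // 2)


def depth_to_space(x: Tensor) -> Tensor:
    """Exact inverse of :func:`space_to_depth`."""
    b, c4, h, w = x.shape
    if c4 % 4:
        raise ValueError("depth_to_space requires channels divisible by 4")
    c = c4 // 4
    y = x.reshape(b, 2, 2, c, h, w).transpose(0, 3, 4, 1, 5, 2)
    return y.reshape(b, c, 2 * h, 2 * w)


def pixel_shuffle(x: Tensor, s: int) -> Tensor:
    """(B, s^2 C, H, W) -> (B, C, sH, sW), channel groups to sub-pixels."""
    b, cs, h, w = x.shape
    if cs % (s * s):
        raise ValueError(f"pixel_shuffle: {cs} channels not divisible by s^2={s * s}")
    c = cs // (s * s)
    y = x.reshape(b, c, s, s, h, w).transpose(0, 1, 4, 2, 5, 3)
    return y.reshape(b, c, s * h, s * w)


def pixel_unshuffle(x: Tensor, s: int) -> Tensor:
    """Inverse of :func:`pixel_shuffle`."""
    b, c, hs, ws = x.shape
    if hs % s or ws % s:
        raise ValueError("pixel_unshuffle: spatial dims not divisible by s")
    h, w = hs // s, ws // s
    y = x.reshape(b, c, h, s, w, s).transpose(0, 1, 3, 5, 2, 4)
    return y.reshape(b, c * s * s, h, w)


def dropout(x: Tensor, rate: float, rng: np.random.Generator, training: bool) -> Tensor:
    if not training or rate <= 0.0:
        return x
    keep = (rng.random(x.shape) >= rate) / (1.0 - rate)
    return x * Tensor(keep)


def global_avg_pool(x: Tensor) -> Tensor:
    """(B, C, H, W) -> (B, C, 1, 1) spatial mean."""
    return x.mean(axis=(2, 3), keepdims=True)


def global_max_pool(x: Tensor) -> Tensor:
    """(B, C, H, W) -> (B, C, 1, 1) spatial max."""
    return x.max(axis=3, keepdims=True).max(axis=2, keepdims=True)
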