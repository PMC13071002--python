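"""A compact three-scale one-stage detector assembling the three blocks.

The graph follows the standard small-object recipe: a progressively
downsampling backbone (strides 8 / 16 / 32), a path-aggregation neck
(top-down then bottom-up fusion), and per-scale heads predicting
objectness, class logits, and a box relative to the cell.  The three
specialized blocks plug in by toggle:

* ``use_aspc`` — every backbone stride-2 downsample becomes an ASPC
  stage (space-to-depth + conv + cascaded attention);
* ``use_dadu`` — both top-down upsamples become DADU blocks;
* ``use_cgwa`` — a CGWA block refines each of the three neck outputs,
  consuming occlusion/density conditions pooled to that scale.

With every toggle off the graph is a plain convolutional baseline.
The width multiplier keeps the model CPU-trainable; channel widths are
(w, 2w, 4w, 8w, 8w) down the backbone and 4w across the neck.

Conditions at inference: the occlusion map is always computable from
the image alone; the density map source is configurable — ``offline_gt``
(precomputed from annotations), ``predicted`` (a small auxiliary head
trained against the offline ground-truth maps), or ``uniform``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .. import nn
from ..aspc import ASPC, ASPCConfig
from ..cgwa import CGWA, CGWAConfig
from ..condition_maps import generate_occlusion_map, pool_condition
from ..dadu import DADU, DADUConfig
from ..nn import Tensor

__all__ = ["ModelConfig", "Detector", "assemble", "count_params_flops"]

STRIDES = (8, 16, 32)


@dataclass
class ModelConfig:
    width: int = 8
    num_classes: int = 3
    input_size: int = 640
    use_aspc: bool = True
    use_cgwa: bool = True
    use_dadu: bool = True
    density_condition_source: str = "predicted"  # {offline_gt, predicted, uniform}
    cgwa_window: int = 7
    cgwa_heads: int = 4
    dadu_groups: int = 4
    aspc_reduction: int = 4
    seed: int = 0

    def __post_init__(self):
        if self.num_classes < 1:
            raise ValueError("num_classes must be >= 1")
        if self.density_condition_source not in ("offline_gt", "predicted", "uniform"):
            raise ValueError(f"unknown density source {self.density_condition_source!r}")


class _ConvBlock(nn.Module):
    def __init__(self, cin, cout, k=3, stride=1, rng=None):
        super().__init__()
        self.conv = nn.Conv2d(cin, cout, k, stride=stride, padding=k // 2, rng=rng)

    def forward(self, x):
        return self.conv(x).relu()


class _Down(nn.Module):
    """One stride-2 stage: ASPC or plain strided conv, per toggle."""

    def __init__(self, cin, cout, use_aspc, reduction, rng, stage: str):
        super().__init__()
        self.stage = stage
        try:
            if use_aspc:
                self.op = ASPC(ASPCConfig(cin, cout, channel_reduction=reduction), rng=rng)
            else:
                self.op = _ConvBlock(cin, cout, 3, stride=2, rng=rng)
        except ValueError as e:
            raise ValueError(f"assembly error at stage {stage!r}: {e}") from e

    def forward(self, x):
        y = self.op(x)
        return y.relu() if isinstance(self.op, ASPC) else y


class _Up(nn.Module):
    """x2 upsample: DADU, or nearest-neighbor when toggled off."""

    def __init__(self, channels, use_dadu, groups, rng, stage: str):
        super().__init__()
        self.is_dadu = use_dadu
        if use_dadu:
            try:
                self.op = DADU(DADUConfig(channels, scale=2, groups=groups), rng=rng)
            except ValueError as e:
                raise ValueError(f"assembly error at stage {stage!r}: {e}") from e
        else:
            self.op = None

    def forward(self, x):
        if self.op is not None:
            return self.op(x)
        idx_h = np.repeat(np.arange(x.shape[2]), 2)
        idx_w = np.repeat(np.arange(x.shape[3]), 2)
        return x[:, :, idx_h][:, :, :, idx_w]


class Detector(nn.Module):
    def __init__(self, config: ModelConfig):
        super().__init__()
        self.config = config
        rng = np.random.default_rng(config.seed)
        w = config.width
        nc = config.num_classes
        r = config.aspc_reduction
        self.stem = _ConvBlock(3, w, rng=rng)
        self.d1 = _Down(w, 2 * w, config.use_aspc, r, rng, "backbone/down1")
        self.d2 = _Down(2 * w, 4 * w, config.use_aspc, r, rng, "backbone/down2")
        self.d3 = _Down(4 * w, 8 * w, config.use_aspc, r, rng, "backbone/down3")  # C3 @ /8
        self.b3 = _ConvBlock(8 * w, 8 * w, rng=rng)
        self.d4 = _Down(8 * w, 8 * w, config.use_aspc, r, rng, "backbone/down4")  # C4 @ /16
        self.b4 = _ConvBlock(8 * w, 8 * w, rng=rng)
        self.d5 = _Down(8 * w, 8 * w, config.use_aspc, r, rng, "backbone/down5")  # C5 @ /32
        self.b5 = _ConvBlock(8 * w, 8 * w, rng=rng)
        # PAN neck: two top-down upsamples, two bottom-up downsamples
        self.up1 = _Up(8 * w, config.use_dadu, config.dadu_groups, rng, "neck/up1")
        self.fuse4 = _ConvBlock(16 * w, 4 * w, rng=rng)
        self.up2 = _Up(4 * w, config.use_dadu, config.dadu_groups, rng, "neck/up2")
        self.fuse3 = _ConvBlock(12 * w, 4 * w, rng=rng)
        self.down_a = _ConvBlock(4 * w, 4 * w, stride=2, rng=rng)
        self.fuse4b = _ConvBlock(8 * w, 4 * w, rng=rng)
        self.down_b = _ConvBlock(4 * w, 4 * w, stride=2, rng=rng)
        self.fuse5b = _ConvBlock(12 * w, 4 * w, rng=rng)
        if config.use_cgwa:
            mk = lambda: CGWA(
                CGWAConfig(4 * w, heads=config.cgwa_heads, window_size=config.cgwa_window), rng=rng
            )
            self.cgwa3, self.cgwa4, self.cgwa5 = mk(), mk(), mk()
        else:
            self.cgwa3 = self.cgwa4 = self.cgwa5 = None
        # CoordConv-style two-layer heads: normalized coordinate channels
        # plus a hidden nonlinearity let each cell's targets be fit
        # quickly at small step budgets
        self.heads = nn.ModuleList(
            [
                nn.Sequential(
                    nn.Conv2d(4 * w + 2, 64, 1, rng=rng),
                    nn.ReLU(),
                    nn.Conv2d(64, 5 + nc, 1, rng=rng),
                )
                for _ in STRIDES
            ]
        )
        for head in self.heads:
            head.layers[-1].bias.data[0] = -4.0  # low objectness prior at init
        # auxiliary density predictor (stride-1, from stem features)
        self.density_head = nn.Sequential(
            nn.Conv2d(w, 8, 3, padding=1, rng=rng),
            nn.ReLU(),
            nn.Conv2d(8, 1, 3, padding=1, rng=rng),
            nn.Sigmoid(),
        )
        self.last_neck_features: list[Tensor] | None = None

    # ------------------------------------------------------------------
    def dadu_instances(self) -> int:
        return sum(1 for m in (self.up1, self.up2) if m.is_dadu and m.op is not None)

    def predict_density(self, stem_feat: Tensor) -> Tensor:
        return self.density_head(stem_feat)

    def forward(
        self,
        x: Tensor,
        occlusion: np.ndarray | None = None,
        density: np.ndarray | None = None,
        images_uint8: np.ndarray | None = None,
        density_gt: np.ndarray | None = None,
    ):
        """Return per-scale raw head maps and the predicted density (if any).

        ``x`` is (B, 3, H, W) in [0, 1].  Conditions may be passed
        explicitly; otherwise they are derived per the config (the
        occlusion map needs ``images_uint8``).
        """
        s = self.stem(x)
        pred_density = None
        if occlusion is None:
            if images_uint8 is None:
                images_uint8 = np.clip(np.round(x.data * 255.0), 0, 255).astype(np.uint8).transpose(0, 2, 3, 1)
            occlusion = np.stack(
                [generate_occlusion_map(images_uint8[i]) for i in range(x.shape[0])]
            )
        if density is None:
            src = self.config.density_condition_source
            if src == "offline_gt":
                if density_gt is None:
                    raise ValueError("density_condition_source='offline_gt' requires density_gt")
                density = np.asarray(density_gt, dtype=np.float64)
            elif src == "predicted":
                pred_density = self.predict_density(s)
                density = pred_density.data.copy()
            else:  # uniform
                density = np.full_like(occlusion, 0.5)
        c2 = self.d2(self.d1(s))
        c3 = self.b3(self.d3(c2))
        c4 = self.b4(self.d4(c3))
        c5 = self.b5(self.d5(c4))
        n4 = self.fuse4(nn.concatenate([self.up1(c5), c4], axis=1))
        n3 = self.fuse3(nn.concatenate([self.up2(n4), c3], axis=1))
        n4b = self.fuse4b(nn.concatenate([self.down_a(n3), n4], axis=1))
        n5b = self.fuse5b(nn.concatenate([self.down_b(n4b), c5], axis=1))
        feats = [n3, n4b, n5b]
        if self.cgwa3 is not None:
            refined = []
            for feat, block in zip(feats, (self.cgwa3, self.cgwa4, self.cgwa5)):
                th, tw = feat.shape[2], feat.shape[3]
                occ_s = pool_condition(occlusion, th, tw)
                den_s = pool_condition(np.clip(density, 0.0, 1.0), th, tw)
                refined.append(block(feat, (occ_s, den_s)))
            feats = refined
        self.last_neck_features = feats
        outputs = []
        for head, f in zip(self.heads, feats):
            fb, _, fh, fw = f.shape
            gy, gx = np.meshgrid(
                (np.arange(fh) + 0.5) / fh * 2 - 1,
                (np.arange(fw) + 0.5) / fw * 2 - 1,
                indexing="ij",
            )
            coords = np.broadcast_to(np.stack([gx, gy])[None], (fb, 2, fh, fw)).copy()
            outputs.append(head(nn.concatenate([f, Tensor(coords)], axis=1)))
        return outputs, pred_density

    # ------------------------------------------------------------------
    def decode(
        self,
        outputs: list[Tensor],
        image_size: int,
        score_threshold: float = 0.25,
    ) -> list[dict]:
        """Raw head maps -> per-image detections (absolute xyxy boxes).

        Score = sigmoid(objectness) * max-class probability.  Channels
        1:5 are distances (l, t, r, b) from the cell center to the box
        edges in stride units (clamped non-negative at decode).
        """
        b = outputs[0].shape[0]
        results = [dict(boxes=[], scores=[], class_ids=[]) for _ in range(b)]
        for out, stride in zip(outputs, STRIDES):
            o = out.data
            obj = 1.0 / (1.0 + np.exp(-np.clip(o[:, 0], -50, 50)))
            ltrb = np.clip(o[:, 1:5], 0.0, None) * stride
            cls = o[:, 5:]
            cls_exp = np.exp(cls - cls.max(axis=1, keepdims=True))
            cls_prob = cls_exp / cls_exp.sum(axis=1, keepdims=True)
            for bi in range(b):
                ys, xs = np.nonzero(obj[bi] >= score_threshold)
                for y, x in zip(ys, xs):
                    ccx, ccy = (x + 0.5) * stride, (y + 0.5) * stride
                    l, t, r, bo = ltrb[bi, :, y, x]
                    cid = int(np.argmax(cls_prob[bi, :, y, x]))
                    score = float(obj[bi, y, x] * cls_prob[bi, cid, y, x])
                    results[bi]["boxes"].append([ccx - l, ccy - t, ccx + r, ccy + bo])
                    results[bi]["scores"].append(score)
                    results[bi]["class_ids"].append(cid)
        for r in results:
            r["boxes"] = np.array(r["boxes"], dtype=np.float64).reshape(-1, 4)
            r["scores"] = np.array(r["scores"], dtype=np.float64)
            r["class_ids"] = np.array(r["class_ids"], dtype=np.int64)
        return results


def assemble(config: ModelConfig) -> Detector:
    """Build the detector graph described by ``config``."""
    return Detector(config)


def count_params_flops(model: Detector, input_size: int | None = None) -> tuple[int, int]:
    """Exact parameter count and multiply-accumulate count of a forward pass.

    MACs are counted analytically inside every convolution and matrix
    product executed during one forward pass on a zero image of the
    given size (deterministic; conditions set to uniform to avoid
    data-dependent work).
    """
    from ..nn import tensor as tensor_mod

    n_params = model.num_parameters()
    size = input_size or model.config.input_size
    x = Tensor(np.zeros((1, 3, size, size)))
    occ = np.zeros((1, 1, size, size))
    den = np.full((1, 1, size, size), 0.5)
    tensor_mod.MAC_COUNTER["enabled"] = True
    tensor_mod.MAC_COUNTER["macs"] = 0
    try:
        was_training = model.training
        model.eval()
        model.forward(x, occlusion=occ, density=den)
        model.train(was_training)
        macs = int(tensor_mod.MAC_COUNTER["macs"])
    finally:
        tensor_mod.MAC_COUNTER["enabled"] = False
    return n_params, macs
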