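"""Tiny-scale CPU training: losses, target assignment, checkpoints.

One-stage detector losses of the conventional kind — binary
cross-entropy objectness over all cells, plus box-offset BCE, log-size
MSE and class cross-entropy at assigned cells.  Each ground-truth box
is assigned to the center cell of the scale whose stride matches its
size.  When the density condition source is ``predicted``, an
auxiliary MSE against the offline ground-truth density maps trains the
density head jointly.  Training is seeded and deterministic per seed.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np

from ..nn import Adam, Tensor
from .data import load_split
from .model import STRIDES, Detector, ModelConfig, assemble

__all__ = ["assign_targets", "detection_loss", "train_tiny", "save_checkpoint", "load_checkpoint"]

# size thresholds (px, box max dim) routing a truth box to a scale
_SCALE_BOUNDS = (20.0, 40.0)
_BOX_WEIGHT = 2.0
_CLS_WEIGHT = 1.0
_DENSITY_WEIGHT = 1.0


def assign_targets(boxes_px: np.ndarray, classes: np.ndarray, image_size: int):
    """Anchor-free assignment: every cell inside a truth box is positive.

    Each truth box is routed to one scale by its size; all cells of
    that scale whose centers fall inside the box become positives and
    regress the distances (l, t, r, b) from the cell center to the box
    edges, in stride units — so duplicate detections of one object
    coincide and are merged by NMS.  When boxes overlap, a cell takes
    the smallest covering box.  Returns one record per positive cell:
    ``(scale, gy, gx, l, t, r, b, class_id)``.
    """
    boxes_px = np.asarray(boxes_px, dtype=np.float64).reshape(-1, 4)
    records: dict[tuple, tuple] = {}
    areas = (boxes_px[:, 2] - boxes_px[:, 0]) * (boxes_px[:, 3] - boxes_px[:, 1])
    order = np.argsort(-areas)  # large first; small overwrite
    for bi in order:
        x1, y1, x2, y2 = boxes_px[bi]
        cid = int(classes[bi])
        m = max(x2 - x1, y2 - y1)
        scale = 0 if m < _SCALE_BOUNDS[0] else (1 if m < _SCALE_BOUNDS[1] else 2)
        stride = STRIDES[scale]
        grid = image_size // stride
        cx, cy = (x1 + x2) / 2, (y1 + y2) / 2
        gx_lo = max(int(np.floor(x1 / stride)), 0)
        gx_hi = min(int(np.ceil(x2 / stride)), grid)
        gy_lo = max(int(np.floor(y1 / stride)), 0)
        gy_hi = min(int(np.ceil(y2 / stride)), grid)
        cells = []
        for gy in range(gy_lo, gy_hi):
            for gx in range(gx_lo, gx_hi):
                ccx, ccy = (gx + 0.5) * stride, (gy + 0.5) * stride
                if x1 <= ccx <= x2 and y1 <= ccy <= y2:
                    cells.append((gy, gx, ccx, ccy))
        if not cells:  # tiny box between cell centers: use the nearest cell
            gx = min(max(int(cx / stride), 0), grid - 1)
            gy = min(max(int(cy / stride), 0), grid - 1)
            cells = [(gy, gx, (gx + 0.5) * stride, (gy + 0.5) * stride)]
        for gy, gx, ccx, ccy in cells:
            l, t = (ccx - x1) / stride, (ccy - y1) / stride
            r, b = (x2 - ccx) / stride, (y2 - ccy) / stride
            records[(scale, gy, gx)] = (scale, gy, gx, l, t, r, b, cid)
    return list(records.values())


def _bce_with_logits(x: Tensor, target: np.ndarray | float) -> Tensor:
    """Numerically stable elementwise BCE on logits."""
    t = Tensor(np.asarray(target, dtype=np.float64))
    return x.relu() - x * t + (1.0 + (-x.abs()).exp()).log()


def _softplus(x: Tensor) -> Tensor:
    return x.relu() + (1.0 + (-x.abs()).exp()).log()


def _focal_obj_loss(x: Tensor, target: np.ndarray, alpha: float = 0.25, gamma: float = 2.0) -> Tensor:
    """Focal binary cross-entropy on objectness logits, summed.

    Down-weights easy negatives so the hard cells ringing each object
    dominate the gradient; normalize by the positive count outside.
    """
    t = Tensor(target)
    p = x.sigmoid()
    pos = t * alpha * (1.0 - p) ** gamma * _softplus(-x)
    neg = (1.0 - t) * (1.0 - alpha) * p ** gamma * _softplus(x)
    return (pos + neg).sum()


def detection_loss(outputs: list[Tensor], targets_per_image: list[list[tuple]], num_classes: int) -> Tensor:
    """Total loss over a batch given per-image assignment records."""
    b = outputs[0].shape[0]
    total = Tensor(0.0)
    for si, out in enumerate(outputs):
        _, ch, gh, gw = out.shape
        obj_target = np.zeros((b, gh, gw))
        bs, ys, xs, ltrb, cids = [], [], [], [], []
        for bi, records in enumerate(targets_per_image):
            for scale, gy, gx, l, t, r, bb, cid in records:
                if scale != si:
                    continue
                obj_target[bi, gy, gx] = 1.0
                bs.append(bi), ys.append(gy), xs.append(gx)
                ltrb.append((l, t, r, bb)), cids.append(cid)
        obj_logits = out[:, 0]
        n_pos_total = sum(len(recs) for recs in targets_per_image)
        total = total + _focal_obj_loss(obj_logits, obj_target) * (1.0 / max(n_pos_total, 1))
        if bs:
            bs_a, ys_a, xs_a = np.array(bs), np.array(ys), np.array(xs)
            pos_box = out[(bs_a, slice(1, 5), ys_a, xs_a)]  # (npos, 4) = (l, t, r, b)
            box_loss = ((pos_box - Tensor(np.array(ltrb))) ** 2.0).mean()
            z = out[(bs_a, slice(5, None), ys_a, xs_a)]  # (npos, nc)
            m = z.max(axis=1, keepdims=True)
            lse = m + (z - m).exp().sum(axis=1, keepdims=True).log()
            zt = z[(np.arange(len(bs)), np.array(cids))]
            ce = (lse.reshape(len(bs)) - zt).mean()
            total = total + _BOX_WEIGHT * box_loss + _CLS_WEIGHT * ce
    return total


def train_tiny(
    model: Detector,
    dataset_dir: str | Path,
    epochs: int = 1,
    seed: int = 0,
    lr: float = 5e-3,
    batch_size: int = 8,
    max_steps: int | None = None,
    split: str = "train",
    grad_clip_norm: float = 5.0,
) -> dict:
    """Seeded small-scale training; returns the loss trace and final state.

    The loss trace is recorded per step; ``max_steps`` caps the total
    number of optimizer updates regardless of ``epochs``.
    """
    samples = load_split(dataset_dir, split)
    if not samples:
        raise ValueError("empty dataset")
    size = samples[0]["image"].shape[0]
    if size != model.config.input_size:
        raise ValueError(
            f"dataset images are {size} px but model.config.input_size is {model.config.input_size}"
        )
    rng = np.random.default_rng(seed)
    opt = Adam(model.parameters(), lr=lr)
    model.train()
    trace: list[float] = []
    step = 0
    nc = model.config.num_classes
    done = False
    for _ in range(epochs):
        order = rng.permutation(len(samples))
        for lo in range(0, len(samples), batch_size):
            batch = [samples[i] for i in order[lo : lo + batch_size]]
            images = np.stack([s["image"] for s in batch])
            x = Tensor(images.transpose(0, 3, 1, 2) / 255.0)
            density_gt = np.stack(
                [
                    s["density"] if s["density"] is not None else np.zeros((1, size, size))
                    for s in batch
                ]
            )
            occlusion = np.stack(
                [
                    s["occlusion"]
                    if s["occlusion"] is not None
                    else np.zeros((1, size, size))
                    for s in batch
                ]
            )
            outputs, pred_density = model.forward(
                x, occlusion=occlusion, images_uint8=images, density_gt=density_gt
            )
            targets = []
            for s in batch:
                boxes_px = np.array([b.to_xyxy(size, size) for b in s["boxes"]]).reshape(-1, 4)
                classes = np.array([b.class_id for b in s["boxes"]], dtype=np.int64)
                targets.append(assign_targets(boxes_px, classes, size))
            loss = detection_loss(outputs, targets, nc)
            if pred_density is not None:
                loss = loss + _DENSITY_WEIGHT * ((pred_density - Tensor(density_gt)) ** 2.0).mean()
            opt.zero_grad()
            loss.backward()
            if grad_clip_norm is not None:
                gsq = sum(
                    float((p.grad**2).sum()) for p in model.parameters() if p.grad is not None
                )
                gnorm = np.sqrt(gsq)
                if gnorm > grad_clip_norm:
                    scale = grad_clip_norm / gnorm
                    for p in model.parameters():
                        if p.grad is not None:
                            p.grad *= scale
            opt.step()
            trace.append(loss.item())
            step += 1
            if max_steps is not None and step >= max_steps:
                done = True
                break
        if done:
            break
    model.eval()
    return {"loss_trace": trace, "steps": step, "state_dict": model.state_dict()}


def save_checkpoint(model: Detector, path: str | Path) -> None:
    """Single-file checkpoint with the config embedded."""
    from dataclasses import asdict

    state = model.state_dict()
    np.savez(path, __config__=json.dumps(asdict(model.config)), **state)


def load_checkpoint(path: str | Path) -> Detector:
    data = np.load(path, allow_pickle=False)
    config = ModelConfig(**json.loads(str(data["__config__"])))
    model = assemble(config)
    model.load_state_dict({k: data[k] for k in data.files if k != "__config__"})
    model.eval()
    return model
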