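"""Gradient-weighted class-activation heatmap for the detector."""

from __future__ import annotations

import numpy as np
from skimage.transform import resize

from ..nn import Tensor
from .model import Detector

__all__ = ["cam_heatmap"]


def cam_heatmap(model: Detector, image: np.ndarray, target_scale: int = 0) -> np.ndarray:
    """Grad-CAM style map in [0, 1] at the image's spatial resolution.

    The objectness logits of the chosen output scale are summed and
    back-propagated to that scale's neck features; channels are
    weighted by their mean gradient, combined, rectified and min-max
    normalized.  A degenerate (constant / zero-gradient) map falls
    back to a uniform 0.5 raster.
    """
    image = np.asarray(image)
    h, w = image.shape[:2]
    was_training = model.training
    model.eval()
    model.zero_grad()
    x = Tensor(image.transpose(2, 0, 1)[None] / 255.0)
    outputs, _ = model.forward(x, images_uint8=image[None])
    feat = model.last_neck_features[target_scale]
    score = outputs[target_scale][:, 0].sum()
    score.backward()
    model.train(was_training)
    grad = feat.grad
    if grad is None or not np.any(grad):
        return np.full((h, w), 0.5)
    weights = grad.mean(axis=(2, 3), keepdims=True)  # (1, C, 1, 1)
    cam = np.clip((weights * feat.data).sum(axis=1)[0], 0.0, None)
    lo, hi = cam.min(), cam.max()
    if hi - lo < 1e-12:
        return np.full((h, w), 0.5)
    cam = (cam - lo) / (hi - lo)
    return np.clip(resize(cam, (h, w), order=1, mode="reflect", anti_aliasing=False), 0.0, 1.0)
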