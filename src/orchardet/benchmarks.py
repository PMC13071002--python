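"""Reproducible study-condition benchmarks.

Self-contained experiment drivers used by the test-suite and the
acceptance script: the synthetic occlusion-regime statistic, the
colorimetric round-trip rate, and the small-scene overfit run that
exercises the fully assembled detector end to end on CPU.
"""

from __future__ import annotations

import tempfile
from dataclasses import replace
from pathlib import Path

import numpy as np

from .detector import (
    DetectionSet,
    ModelConfig,
    assemble,
    evaluate,
    load_split,
    nms,
    train_tiny,
)
from .colorimetry import CLASS_NAMES, classify_box
from .nn import Tensor
from .synthetic_orchard import SceneSpec, render_scene, write_dataset

__all__ = [
    "occlusion_regime_share",
    "colorimetry_roundtrip_rate",
    "overfit_small_scenes",
    "easy_scene_spec",
]


def occlusion_regime_share(
    n_scenes: int = 200, seed: int = 0, spec: SceneSpec | None = None
) -> float:
    """Fraction of fruits with more than 30% of their area occluded.

    Rendered under the default scene regime (320 px canvases keep the
    statistic identical in expectation while staying fast on CPU).
    """
    base = spec or SceneSpec(image_size=320, n_fruits=12)
    fractions: list[float] = []
    for i in range(n_scenes):
        _, truth = render_scene(replace(base, seed=seed + i))
        fractions.extend(truth.occluded_fraction)
    return float(np.mean(np.asarray(fractions) > 0.3))


def colorimetry_roundtrip_rate(n_scenes: int = 25, seed: int = 0) -> float:
    """Share of unoccluded synthetic fruits classified as their class."""
    base = SceneSpec(image_size=320, n_fruits=10, occluder_density=0.0)
    ok = total = 0
    for i in range(n_scenes):
        image, truth = render_scene(replace(base, seed=seed + i))
        for box, frac in zip(truth.boxes, truth.occluded_fraction):
            if frac > 0:
                continue  # covered by a neighboring fruit
            total += 1
            label, _ = classify_box(image, box)
            ok += label is CLASS_NAMES[box.class_id]
    return ok / max(total, 1)


def easy_scene_spec(image_size: int = 96) -> SceneSpec:
    """Well-separated, unoccluded fruits: the overfit sanity regime."""
    return SceneSpec(
        image_size=image_size,
        n_fruits=4,
        radius_range=(6.0, 11.0),
        cluster_count=4,
        cluster_spread=30.0,
        occluder_density=0.0,
    )


def overfit_small_scenes(
    seed: int = 0,
    n_scenes: int = 8,
    steps: int = 200,
    width: int = 8,
    image_size: int = 96,
    lr: float = 5e-3,
    out_dir: str | Path | None = None,
) -> dict:
    """Train the full model (all toggles) to memorize a few easy scenes.

    Returns the loss trace endpoints and the evaluation metrics of the
    trained model on its own training scenes.
    """
    base = easy_scene_spec(image_size)
    scenes = [replace(base, seed=100 + seed * 1000 + i) for i in range(n_scenes)]
    work = Path(out_dir) if out_dir else Path(tempfile.mkdtemp(prefix="orchardet_overfit_"))
    write_dataset(scenes, work, split=(1.0, 0.0, 0.0))
    model = assemble(ModelConfig(width=width, input_size=image_size, seed=seed))
    result = train_tiny(
        model, work, epochs=steps, seed=seed, lr=lr, batch_size=n_scenes, max_steps=steps
    )
    samples = load_split(work, "train")
    dets, tb, tc = [], [], []
    for s in samples:
        x = Tensor(s["image"].transpose(2, 0, 1)[None] / 255.0)
        outs, _ = model.forward(x, occlusion=s["occlusion"][None], images_uint8=s["image"][None])
        raw = model.decode(outs, image_size, score_threshold=0.1)[0]
        dets.append(nms(DetectionSet(raw["boxes"], raw["scores"], raw["class_ids"])))
        size = image_size
        tb.append(np.array([b.to_xyxy(size, size) for b in s["boxes"]]).reshape(-1, 4))
        tc.append(np.array([b.class_id for b in s["boxes"]], dtype=np.int64))
    metrics = evaluate(dets, tb, tc, num_classes=model.config.num_classes)
    return {
        "model": model,
        "loss_first": result["loss_trace"][0],
        "loss_last": result["loss_trace"][-1],
        "map50": metrics["mAP@0.5"],
        "precision": metrics["precision"],
        "recall": metrics["recall"],
        "f1": metrics["F1"],
    }
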