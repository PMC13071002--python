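"""Loading datasets written by :func:`orchardet.synthetic_orchard.write_dataset`."""

from __future__ import annotations

import json
from pathlib import Path

import imageio.v3 as iio
import numpy as np

from ..boxes import read_yolo_labels

__all__ = ["load_split"]


def load_split(dataset_dir: str | Path, split: str = "train") -> list[dict]:
    """Return a list of samples: image (H, W, 3 uint8), boxes, conditions."""
    dataset_dir = Path(dataset_dir)
    manifest_path = dataset_dir / "manifest.json"
    if not manifest_path.exists():
        raise ValueError(f"no manifest.json under {dataset_dir}")
    manifest = json.loads(manifest_path.read_text())
    stems = manifest["splits"].get(split, [])
    if not stems:
        raise ValueError(f"split {split!r} is empty in {dataset_dir}")
    samples = []
    for stem in stems:
        base = dataset_dir / split
        image = iio.imread(base / "images" / f"{stem}.png")
        boxes = read_yolo_labels(base / "labels" / f"{stem}.txt")
        occ_path = base / "conditions" / f"{stem}.occlusion.npy"
        den_path = base / "conditions" / f"{stem}.density.npy"
        occlusion = np.load(occ_path).astype(np.float64) if occ_path.exists() else None
        density = np.load(den_path).astype(np.float64) if den_path.exists() else None
        samples.append(
            dict(stem=stem, image=image, boxes=boxes, occlusion=occlusion, density=density)
        )
    return samples
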