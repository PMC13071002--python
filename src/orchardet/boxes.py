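"""Bounding-box annotations in YOLO normalized format, plus IoU helpers.

A label file holds one object per line: ``class cx cy w h`` with the
four geometry fields as floats normalized to [0, 1] relative to the
image, LF line endings.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

__all__ = ["BoxAnnotation", "read_yolo_labels", "write_yolo_labels", "iou_matrix"]


@dataclass(frozen=True)
class BoxAnnotation:
    """One object: integer class id and normalized center/size box."""

    class_id: int
    cx: float
    cy: float
    w: float
    h: float

    def validate(self) -> "BoxAnnotation":
        if not (0.0 <= self.cx <= 1.0 and 0.0 <= self.cy <= 1.0):
            raise ValueError(f"box center ({self.cx}, {self.cy}) outside [0,1]^2: {self}")
        if self.w < 0 or self.h < 0:
            raise ValueError(f"negative box size: {self}")
        return self

    def to_xyxy(self, width: int, height: int) -> tuple[float, float, float, float]:
        """Denormalize to absolute (x1, y1, x2, y2) pixel corners."""
        x1 = (self.cx - self.w / 2) * width
        y1 = (self.cy - self.h / 2) * height
        x2 = (self.cx + self.w / 2) * width
        y2 = (self.cy + self.h / 2) * height
        return x1, y1, x2, y2


def read_yolo_labels(path: str | Path) -> list[BoxAnnotation]:
    boxes = []
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if not line:
            continue
        parts = line.split()
        if len(parts) != 5:
            raise ValueError(f"malformed YOLO label line in {path!s}: {line!r}")
        boxes.append(
            BoxAnnotation(int(parts[0]), *(float(p) for p in parts[1:])).validate()
        )
    return boxes


def write_yolo_labels(path: str | Path, boxes: list[BoxAnnotation]) -> None:
    lines = [f"{b.class_id} {b.cx:.6f} {b.cy:.6f} {b.w:.6f} {b.h:.6f}" for b in boxes]
    Path(path).write_text("\n".join(lines) + ("\n" if lines else ""))


def iou_matrix(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Pairwise IoU between two (N, 4) / (M, 4) xyxy arrays."""
    a = np.asarray(a, dtype=np.float64).reshape(-1, 4)
    b = np.asarray(b, dtype=np.float64).reshape(-1, 4)
    x1 = np.maximum(a[:, None, 0], b[None, :, 0])
    y1 = np.maximum(a[:, None, 1], b[None, :, 1])
    x2 = np.minimum(a[:, None, 2], b[None, :, 2])
    y2 = np.minimum(a[:, None, 3], b[None, :, 3])
    inter = np.clip(x2 - x1, 0, None) * np.clip(y2 - y1, 0, None)
    area_a = np.clip(a[:, 2] - a[:, 0], 0, None) * np.clip(a[:, 3] - a[:, 1], 0, None)
    area_b = np.clip(b[:, 2] - b[:, 0], 0, None) * np.clip(b[:, 3] - b[:, 1], 0, None)
    union = area_a[:, None] + area_b[None, :] - inter
    return np.where(union > 0, inter / np.maximum(union, 1e-12), 0.0)
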