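"""Annotated-image container shared by I/O, augmentation and training.

Boxes are stored 0-based, half-open, absolute-pixel corner coordinates
``(x0, y0, x1, y1)`` with ``x1 > x0`` and ``y1 > y0``; format
conversions (VOC's 1-based inclusive corners, COCO's xywh) happen at
the I/O boundary only.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

CLASS_NAMES = ("chicken_face",)


@dataclass
class AnnotatedImage:
    image: np.ndarray                      # (H, W, 3) uint8 RGB
    boxes: np.ndarray                      # (n, 4) float32 corners, half-open
    labels: np.ndarray = None              # (n,) int class ids
    source_id: str = ""
    split: str | None = None
    provenance: str | None = None          # augmentation ancestry, if any

    def __post_init__(self):
        self.image = np.ascontiguousarray(self.image, dtype=np.uint8)
        self.boxes = np.asarray(self.boxes, dtype=np.float32).reshape(-1, 4)
        if self.labels is None:
            self.labels = np.zeros(len(self.boxes), dtype=np.int64)
        self.labels = np.asarray(self.labels, dtype=np.int64)
        h, w = self.image.shape[:2]
        if len(self.boxes):
            if (self.boxes[:, 0] < 0).any() or (self.boxes[:, 1] < 0).any() \
                    or (self.boxes[:, 2] > w).any() or (self.boxes[:, 3] > h).any():
                raise ValueError("boxes must lie within image bounds")
            wh = self.boxes[:, 2:] - self.boxes[:, :2]
            if (wh < 1.0).any():
                raise ValueError("boxes must be at least 1 pixel wide and tall")

    @property
    def height(self) -> int:
        return self.image.shape[0]

    @property
    def width(self) -> int:
        return self.image.shape[1]
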