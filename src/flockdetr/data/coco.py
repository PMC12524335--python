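"""COCO-format detection ground truth (JSON dicts)."""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np

from .annotations import CLASS_NAMES, AnnotatedImage


def to_coco_json(dataset: list[AnnotatedImage]) -> dict:
    """Serialize a dataset to the COCO 'images/annotations/categories'
    structure with contiguous 1-based ids; areas are w*h in pixels."""
    images, annotations = [], []
    ann_id = 1
    for img_id, ann in enumerate(dataset, start=1):
        images.append({
            "id": img_id,
            "file_name": (ann.source_id or f"image_{img_id}") + ".png",
            "width": ann.width,
            "height": ann.height,
        })
        for box, label in zip(ann.boxes, ann.labels):
            x0, y0, x1, y1 = (float(v) for v in box)
            annotations.append({
                "id": ann_id,
                "image_id": img_id,
                "category_id": int(label) + 1,
                "bbox": [x0, y0, x1 - x0, y1 - y0],
                "area": (x1 - x0) * (y1 - y0),
                "iscrowd": 0,
            })
            ann_id += 1
    categories = [{"id": i + 1, "name": n} for i, n in enumerate(CLASS_NAMES)]
    return {"images": images, "annotations": annotations, "categories": categories}


def from_coco_json(doc: dict | str | Path,
                   images: dict[int, np.ndarray] | None = None) -> list[AnnotatedImage]:
    """Inverse of :func:`to_coco_json`; pixel arrays may be supplied per
    image id, otherwise zero images of the declared size are attached."""
    if not isinstance(doc, dict):
        doc = json.loads(Path(doc).read_text())
    by_img: dict[int, list] = {im["id"]: [] for im in doc["images"]}
    for a in doc["annotations"]:
        by_img[a["image_id"]].append(a)
    out = []
    for im in doc["images"]:
        anns = by_img[im["id"]]
        boxes = np.array(
            [[a["bbox"][0], a["bbox"][1],
              a["bbox"][0] + a["bbox"][2], a["bbox"][1] + a["bbox"][3]]
             for a in anns], dtype=np.float32).reshape(-1, 4)
        labels = np.array([a["category_id"] - 1 for a in anns], dtype=np.int64)
        pixels = None if images is None else images.get(im["id"])
        if pixels is None:
            pixels = np.zeros((im["height"], im["width"], 3), dtype=np.uint8)
        out.append(AnnotatedImage(image=pixels, boxes=boxes, labels=labels,
                                  source_id=Path(im["file_name"]).stem))
    return out
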