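"""Pascal VOC XML annotation I/O (the LabelImg dialect).

VOC stores 1-based inclusive corners: internal half-open box
``(x0, y0, x1, y1)`` maps to ``xmin = x0 + 1, ymin = y0 + 1,
xmax = x1, ymax = y1`` and back.  Round-trips are lossless for
integer-valued boxes.
"""

from __future__ import annotations

import xml.etree.ElementTree as ET
from pathlib import Path

import numpy as np

from .annotations import CLASS_NAMES, AnnotatedImage


def write_voc_xml(ann: AnnotatedImage, path: str | Path,
                  image_filename: str | None = None) -> None:
    root = ET.Element("annotation")
    ET.SubElement(root, "folder").text = "images"
    ET.SubElement(root, "filename").text = image_filename or (ann.source_id + ".png")
    size = ET.SubElement(root, "size")
    ET.SubElement(size, "width").text = str(ann.width)
    ET.SubElement(size, "height").text = str(ann.height)
    ET.SubElement(size, "depth").text = "3"
    ET.SubElement(root, "segmented").text = "0"
    for box, label in zip(ann.boxes, ann.labels):
        obj = ET.SubElement(root, "object")
        ET.SubElement(obj, "name").text = CLASS_NAMES[int(label)] \
            if int(label) < len(CLASS_NAMES) else str(int(label))
        ET.SubElement(obj, "pose").text = "Unspecified"
        ET.SubElement(obj, "truncated").text = "0"
        ET.SubElement(obj, "difficult").text = "0"
        bb = ET.SubElement(obj, "bndbox")
        ET.SubElement(bb, "xmin").text = str(int(round(box[0])) + 1)
        ET.SubElement(bb, "ymin").text = str(int(round(box[1])) + 1)
        ET.SubElement(bb, "xmax").text = str(int(round(box[2])))
        ET.SubElement(bb, "ymax").text = str(int(round(box[3])))
    ET.indent(root)
    ET.ElementTree(root).write(path, encoding="unicode", xml_declaration=False)


def read_voc_xml(path: str | Path, image: np.ndarray | None = None) -> AnnotatedImage:
    """Parse one VOC file.  If no pixel array is supplied, a zero image
    of the declared size is attached (annotation-only use)."""
    try:
        root = ET.parse(str(path)).getroot()
    except ET.ParseError as exc:
        raise ValueError(f"malformed VOC XML at {path}: {exc}") from exc
    size = root.find("size")
    w, h = int(size.findtext("width")), int(size.findtext("height"))
    boxes, labels = [], []
    for obj in root.findall("object"):
        name = obj.findtext("name")
        bb = obj.find("bndbox")
        xmin = float(bb.findtext("xmin"))
        ymin = float(bb.findtext("ymin"))
        xmax = float(bb.findtext("xmax"))
        ymax = float(bb.findtext("ymax"))
        boxes.append([xmin - 1.0, ymin - 1.0, xmax, ymax])
        labels.append(CLASS_NAMES.index(name) if name in CLASS_NAMES else 0)
    if image is None:
        image = np.zeros((h, w, 3), dtype=np.uint8)
    return AnnotatedImage(
        image=image,
        boxes=np.array(boxes, dtype=np.float32).reshape(-1, 4),
        labels=np.array(labels, dtype=np.int64),
        source_id=Path(root.findtext("filename") or str(path)).stem,
    )
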