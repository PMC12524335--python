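"""Training-set augmentations: rotation, salt-and-pepper noise, and
gamma/HSV illumination jitter.

The suite emulates the nuisances of barn imagery: head-pose rotation
(+-45 deg), sensor dust and aging (impulse noise at 0.5-3% density),
and illumination drift (gamma 0.5-1.5 combined with +-20% HSV value
scaling).  Every operation preserves image dimensions; only rotation
touches the boxes (axis-aligned hull of the rotated corners, clipped,
with sub-pixel boxes dropped).
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage
from skimage import color

from .annotations import AnnotatedImage

ROTATE_RANGE = (-45.0, 45.0)
SP_DENSITY_RANGE = (0.005, 0.03)
GAMMA_RANGE = (0.5, 1.5)
VSHIFT_RANGE = (-0.2, 0.2)


def _rotate_boxes(boxes: np.ndarray, angle_deg: float, cx: float, cy: float,
                  w: int, h: int) -> np.ndarray:
    """Axis-aligned hull of each box's corners rotated about (cx, cy).

    The image rotation maps content by -angle in array coordinates (y
    down); the matching point transform rotates corners by the same
    screen-space angle.
    """
    theta = np.deg2rad(angle_deg)
    # matches scipy.ndimage.rotate(angle, axes=(1, 0)) content motion
    rot = np.array([[np.cos(theta), np.sin(theta)],
                    [-np.sin(theta), np.cos(theta)]])
    out, kept = [], []
    for idx, (x0, y0, x1, y1) in enumerate(boxes):
        corners = np.array([[x0, y0], [x1, y0], [x0, y1], [x1, y1]]) - (cx, cy)
        rc = corners @ rot.T + (cx, cy)
        nx0, ny0 = rc.min(axis=0)
        nx1, ny1 = rc.max(axis=0)
        nx0, ny0 = max(nx0, 0.0), max(ny0, 0.0)
        nx1, ny1 = min(nx1, float(w)), min(ny1, float(h))
        if nx1 - nx0 >= 1.0 and ny1 - ny0 >= 1.0:
            out.append([nx0, ny0, nx1, ny1])
            kept.append(idx)
    return np.array(out, dtype=np.float32).reshape(-1, 4), np.array(kept, dtype=int)


def augment_rotate(ann: AnnotatedImage, rng: np.random.Generator,
                   angle_range: tuple[float, float] = ROTATE_RANGE,
                   angle: float | None = None) -> AnnotatedImage:
    if angle is None:
        angle = float(rng.uniform(*angle_range))
    h, w = ann.image.shape[:2]
    if angle == 0.0:
        img = ann.image.copy()
    else:
        # ndimage.rotate with positive angle turns content counter-clockwise
        # in display coordinates; black fill outside the frame.
        img = ndimage.rotate(ann.image, angle, axes=(1, 0), reshape=False,
                             order=1, mode="constant", cval=0.0)
        img = np.clip(img, 0, 255).astype(np.uint8)
    # boxes live in half-open edge coordinates, whose rotation centre is
    # (w/2, h/2) -- equivalent to the pixel-centre rotation the image sees
    boxes, kept = _rotate_boxes(ann.boxes, angle, w / 2.0, h / 2.0, w, h)
    labels = ann.labels[kept] if len(kept) else np.zeros(0, dtype=np.int64)
    return AnnotatedImage(image=img, boxes=boxes, labels=labels,
                          source_id=ann.source_id,
                          provenance=f"{ann.source_id}:rotate{angle:+.1f}")


def augment_salt_pepper(ann: AnnotatedImage, rng: np.random.Generator,
                        density: float | None = None,
                        density_range: tuple[float, float] = SP_DENSITY_RANGE
                        ) -> AnnotatedImage:
    if density is None:
        density = float(rng.uniform(*density_range))
    img = ann.image.copy()
    if density > 0:
        h, w = img.shape[:2]
        hit = rng.random((h, w)) < density
        salt = rng.random((h, w)) < 0.5
        img[hit & salt] = 255
        img[hit & ~salt] = 0
    return AnnotatedImage(image=img, boxes=ann.boxes.copy(),
                          labels=ann.labels.copy(), source_id=ann.source_id,
                          provenance=f"{ann.source_id}:saltpepper{density:.3f}")


def augment_gamma_hsv(ann: AnnotatedImage, rng: np.random.Generator,
                      gamma: float | None = None, v_shift: float | None = None
                      ) -> AnnotatedImage:
    if gamma is None:
        gamma = float(rng.uniform(*GAMMA_RANGE))
    if v_shift is None:
        v_shift = float(rng.uniform(*VSHIFT_RANGE))
    hsv = color.rgb2hsv(ann.image)
    v = hsv[..., 2]
    v = np.clip(np.power(np.clip(v, 0.0, 1.0), gamma) * (1.0 + v_shift), 0.0, 1.0)
    hsv[..., 2] = v
    img = np.clip(np.rint(color.hsv2rgb(hsv) * 255.0), 0, 255).astype(np.uint8)
    return AnnotatedImage(image=img, boxes=ann.boxes.copy(),
                          labels=ann.labels.copy(), source_id=ann.source_id,
                          provenance=f"{ann.source_id}:gamma{gamma:.2f}v{v_shift:+.2f}")


STRATEGIES = {
    "rotate": augment_rotate,
    "salt_pepper": augment_salt_pepper,
    "gamma_hsv": augment_gamma_hsv,
}


def build_augmented_trainset(trainset: list[AnnotatedImage], n_extra: int,
                             rng: np.random.Generator) -> list[AnnotatedImage]:
    """Append ``n_extra`` augmented copies (source drawn with
    replacement, strategy uniform among the three); originals untouched."""
    out = list(trainset)
    names = sorted(STRATEGIES)
    for _ in range(n_extra):
        src = trainset[int(rng.integers(len(trainset)))]
        strategy = names[int(rng.integers(len(names)))]
        out.append(STRATEGIES[strategy](src, rng))
    return out
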