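"""Synthetic dense-flock scene generator.

Renders barn-like scenes of elliptical poultry "faces" -- a feathered
ellipse with a comb arc on top, an eye dot and a beak wedge -- over a
textured litter background, across three growth-stage size regimes:

* ``brooding``  : many tiny faces, heavy crowding,
* ``growing``   : mid-sized faces, moderate crowding,
* ``finisher``  : few large, well-separated faces.

Faces are drawn back-to-front, so a later face partially occludes
earlier ones; the ``occlusion`` level bounds the pairwise IoU of the
full face boxes allowed during placement (0 forces disjoint faces).
Emitted bounding boxes are the exact extents of each face's *visible*
pixels, taken from the instance ownership map, so re-deriving boxes
from the rendered masks reproduces them bit for bit.  Every scene is a
pure function of its spec (including the seed).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .annotations import AnnotatedImage

STAGE_SCALE = {
    "brooding": (0.035, 0.080),
    "growing": (0.070, 0.150),
    "finisher": (0.130, 0.260),
}
STAGE_FACES = {"brooding": (12, 22), "growing": (6, 12), "finisher": (3, 7)}


@dataclass(frozen=True)
class FlockSceneSpec:
    stage: str = "growing"
    n_faces: int = 8
    image_size: int = 640
    scale_range: tuple[float, float] | None = None   # fraction of image side
    occlusion: float = 0.2                           # max pairwise box IoU
    illumination_gamma: float = 1.0
    noise: float = 0.0                               # gaussian std, fraction of 255
    seed: int = 0

    def __post_init__(self):
        if self.stage not in STAGE_SCALE:
            raise ValueError(f"unknown stage {self.stage!r}")
        if self.n_faces < 1:
            raise ValueError("n_faces must be >= 1")
        if not 0.0 <= self.occlusion <= 1.0:
            raise ValueError("occlusion must be in [0, 1]")

    @property
    def scales(self) -> tuple[float, float]:
        return self.scale_range or STAGE_SCALE[self.stage]


def _box_iou(a, b) -> float:
    ix = max(0.0, min(a[2], b[2]) - max(a[0], b[0]))
    iy = max(0.0, min(a[3], b[3]) - max(a[1], b[1]))
    inter = ix * iy
    ua = (a[2] - a[0]) * (a[3] - a[1]) + (b[2] - b[0]) * (b[3] - b[1]) - inter
    return inter / ua if ua > 0 else 0.0


def _face_geometry(rng: np.random.Generator, size_px: float):
    a = 0.5 * size_px * rng.uniform(0.8, 1.0)      # semi-axis along x'
    b = 0.5 * size_px                               # semi-axis along y'
    phi = rng.uniform(-0.5, 0.5)                    # rotation, radians
    return a, b, phi


def _render_face(H, W, cx, cy, a, b, phi):
    """Boolean mask and color map of one face on the full canvas."""
    # local window generous enough for comb and beak
    r = int(np.ceil(max(a, b) * 1.7)) + 2
    x0, x1 = max(0, int(cx) - r), min(W, int(cx) + r + 1)
    y0, y1 = max(0, int(cy) - r), min(H, int(cy) + r + 1)
    if x1 <= x0 or y1 <= y0:
        return None
    ys, xs = np.mgrid[y0:y1, x0:x1]
    dx, dy = xs - cx, ys - cy
    c, s = np.cos(phi), np.sin(phi)
    xr = c * dx + s * dy
    yr = -s * dx + c * dy

    ellipse = (xr / a) ** 2 + (yr / b) ** 2 <= 1.0
    # comb: three bumps along the top rim
    comb = np.zeros_like(ellipse)
    for t in (-0.45, 0.0, 0.45):
        ccx, ccy = t * a, -b * 0.95
        comb |= (xr - ccx) ** 2 + (yr - ccy) ** 2 <= (0.22 * b) ** 2
    # beak: wedge protruding along +x'
    u = (xr - 0.70 * a) / (0.55 * a)
    beak = (u >= 0) & (u <= 1.0) & (np.abs(yr) <= 0.25 * b * (1.0 - u))
    mask = ellipse | comb | beak

    colors = np.zeros(mask.shape + (3,), dtype=np.float32)
    colors[ellipse] = (228.0, 222.0, 205.0)                  # pale feathers
    shade = np.clip(1.0 - 0.25 * (yr / b), 0.75, 1.1)
    colors[..., 0] *= shade
    colors[..., 1] *= shade
    colors[..., 2] *= shade
    colors[comb] = (185.0, 45.0, 40.0)
    colors[beak] = (205.0, 165.0, 60.0)
    eye = (xr - 0.35 * a) ** 2 + (yr + 0.25 * b) ** 2 <= (0.10 * b) ** 2
    colors[eye & ellipse] = (25.0, 20.0, 18.0)
    return (y0, y1, x0, x1), mask, colors


def _background(rng: np.random.Generator, H: int, W: int) -> np.ndarray:
    base = rng.uniform(95.0, 125.0)
    img = np.empty((H, W, 3), dtype=np.float32)
    img[..., 0] = base + 18.0
    img[..., 1] = base
    img[..., 2] = base - 25.0
    lowfreq = ndimage.gaussian_filter(rng.normal(0.0, 1.0, (H, W)), max(H / 16, 2))
    img += (lowfreq * 60.0)[..., None]
    img += rng.normal(0.0, 6.0, (H, W, 1))
    # litter speckles
    n_speck = (H * W) // 400
    sy = rng.integers(0, H, n_speck)
    sx = rng.integers(0, W, n_speck)
    img[sy, sx] += rng.uniform(-40.0, 40.0, (n_speck, 1))
    return img


def generate_flock_scene(spec: FlockSceneSpec, return_masks: bool = False):
    """Render one scene; returns an :class:`AnnotatedImage` (and the
    per-instance visible masks when ``return_masks`` is set)."""
    rng = np.random.default_rng(spec.seed)
    H = W = spec.image_size
    img = _background(rng, H, W)
    owner = np.full((H, W), -1, dtype=np.int32)

    lo, hi = spec.scales
    placed_boxes: list[tuple] = []
    faces = []
    for i in range(spec.n_faces):
        ok = False
        for _ in range(300):
            size_px = rng.uniform(lo, hi) * spec.image_size
            a, b, phi = _face_geometry(rng, size_px)
            m = max(a, b) * 1.2
            cx = rng.uniform(m, W - m)
            cy = rng.uniform(m, H - m)
            cand = (cx - m, cy - m, cx + m, cy + m)
            if all(_box_iou(cand, pb) <= spec.occlusion + 1e-9
                   for pb in placed_boxes):
                ok = True
                break
        if not ok:
            warnings.warn(
                f"could not place face {i} within the occlusion budget; "
                "emitting a best-effort scene with fewer faces")
            continue
        placed_boxes.append(cand)
        faces.append((cx, cy, a, b, phi))

    for idx, (cx, cy, a, b, phi) in enumerate(faces):
        rendered = _render_face(H, W, cx, cy, a, b, phi)
        if rendered is None:
            continue
        (y0, y1, x0, x1), mask, colors = rendered
        region_owner = owner[y0:y1, x0:x1]
        region_img = img[y0:y1, x0:x1]
        region_owner[mask] = idx
        region_img[mask] = colors[mask]

    boxes, labels, masks = [], [], []
    for idx in range(len(faces)):
        vis = owner == idx
        ys, xs = np.nonzero(vis)
        if len(xs) == 0:
            continue
        x0f, x1f = float(xs.min()), float(xs.max() + 1)
        y0f, y1f = float(ys.min()), float(ys.max() + 1)
        if x1f - x0f < 1.0 or y1f - y0f < 1.0:
            continue
        boxes.append([x0f, y0f, x1f, y1f])
        labels.append(0)
        if return_masks:
            masks.append(vis)

    if spec.illumination_gamma != 1.0:
        img = 255.0 * np.power(np.clip(img, 0.0, 255.0) / 255.0,
                               spec.illumination_gamma)
    if spec.noise > 0:
        img = img + rng.normal(0.0, spec.noise * 255.0, img.shape)
    ann = AnnotatedImage(
        image=np.clip(np.rint(img), 0, 255).astype(np.uint8),
        boxes=np.array(boxes, dtype=np.float32).reshape(-1, 4),
        labels=np.array(labels, dtype=np.int64),
        source_id=f"{spec.stage}_{spec.seed:06d}",
    )
    return (ann, masks) if return_masks else ann


def generate_flock_dataset(n_images: int, stage: str = "growing",
                           base_seed: int = 0, image_size: int = 640,
                           occlusion: float = 0.2, noise: float = 0.0,
                           gamma: float = 1.0,
                           n_faces: tuple[int, int] | None = None
                           ) -> list[AnnotatedImage]:
    """A dataset of scenes with per-image seeds derived from base_seed;
    face counts are drawn per image from the stage's typical range."""
    lo, hi = n_faces or STAGE_FACES[stage]
    out = []
    for i in range(n_images):
        seed = base_seed * 100003 + i
        count = int(np.random.default_rng(seed ^ 0x5EED).integers(lo, hi + 1))
        spec = FlockSceneSpec(stage=stage, n_faces=count, image_size=image_size,
                              occlusion=occlusion, noise=noise,
                              illumination_gamma=gamma, seed=seed)
        out.append(generate_flock_scene(spec))
    return out


def generate_easy_toy_dataset(n_images: int, base_seed: int = 0,
                              image_size: int = 160) -> list[AnnotatedImage]:
    """Easy recovery-benchmark scenes: one to three large, unoccluded
    finisher-stage faces per small image."""
    return generate_flock_dataset(
        n_images, stage="finisher", base_seed=base_seed, image_size=image_size,
        occlusion=0.0, n_faces=(1, 3))
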