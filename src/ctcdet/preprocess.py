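"""Intensity transforms, patch extraction and box-aware augmentation.

The two intensity operations are the classic point transforms used to tame
bright-field exposure before detection: a power-law (gamma) transform
``O = I**gamma`` applied on the normalized [0, 1] scale, and a linear
histogram normalization ``O = (O_max - O_min) / (I_max - I_min) * (I - I_min)
+ O_min`` that stretches the observed intensity range onto a target range.
Patch extraction crops fixed-size training patches from the central region of
a full field; augmentation applies translation / scaling / flips to image and
boxes consistently.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from skimage.transform import resize as _sk_resize

from .imaging_io import Annotation, BoundingBox, RasterImage

__all__ = [
    "GammaParams", "NormalizationParams", "AugmentationSpec",
    "gamma_transform", "histogram_normalize", "extract_patches", "augment",
    "DEFAULT_RETENTION",
]

#: Fraction of a box's area that must survive clipping for the box to be kept.
DEFAULT_RETENTION = 0.5


@dataclass(frozen=True)
class GammaParams:
    gamma: float = 1.5

    def __post_init__(self):
        if self.gamma <= 0:
            raise ValueError("gamma must be positive")


@dataclass(frozen=True)
class NormalizationParams:
    out_range: tuple[float, float] = (0.0, 255.0)
    in_range: tuple[float, float] | None = None  # None -> from image

    def __post_init__(self):
        if self.out_range[1] <= self.out_range[0]:
            raise ValueError("O_max must exceed O_min")
        if self.in_range is not None and self.in_range[1] <= self.in_range[0]:
            raise ValueError("I_max must exceed I_min")


@dataclass(frozen=True)
class AugmentationSpec:
    translate: tuple[int, int] = (0, 0)   # (dx, dy) pixels
    scale: float = 1.0                    # in (0, 1]
    hflip: bool = False                   # left-right flip
    mirror: bool = False                  # up-down mirror
    retention: float = DEFAULT_RETENTION

    def __post_init__(self):
        if not (0.0 < self.scale <= 1.0):
            raise ValueError("scale must lie in (0, 1]")
        if any(int(t) != t for t in self.translate):
            raise ValueError("translation offsets must be integers")


def gamma_transform(image: RasterImage, params: GammaParams) -> RasterImage:
    """Power-law intensity transform on normalized pixels; gamma > 1 darkens."""
    if not image.is_normalized:
        raise ValueError("gamma_transform expects a normalized [0, 1] image")
    px = image.pixels
    if px.min() < 0.0 or px.max() > 1.0:
        raise ValueError("pixels outside [0, 1]")
    return RasterImage(np.power(px, params.gamma), image.bit_depth)


def histogram_normalize(image: RasterImage, params: NormalizationParams) -> RasterImage:
    """Linear range stretch from the observed (or explicit) intensity range."""
    px = image.pixels.astype(np.float64)
    if params.in_range is None:
        imin, imax = float(px.min()), float(px.max())
        if imax == imin:
            raise ValueError("constant image: I_max equals I_min")
    else:
        imin, imax = params.in_range
    omin, omax = params.out_range
    out = (omax - omin) / (imax - imin) * (px - imin) + omin
    return RasterImage(out, image.bit_depth)


def _transfer_boxes(boxes: list[BoundingBox], dx: float, dy: float,
                    width: float, height: float, retention: float) -> list[BoundingBox]:
    kept = []
    for box in boxes:
        moved = box.shifted(dx, dy)
        clipped = moved.clipped(width, height)
        if clipped is not None and clipped.area >= retention * moved.area:
            kept.append(clipped)
    return kept


def extract_patches(image: RasterImage, annotation: Annotation, patch_size: int = 300,
                    center_size: int = 850, count: int = 30, seed: int = 0,
                    retention: float = DEFAULT_RETENTION,
                    min_cells: int | None = None, max_cells: int | None = None,
                    ) -> list[tuple[RasterImage, Annotation]]:
    """Randomly crop ``count`` patches from the central region of a field.

    Offsets are drawn uniformly so every patch lies fully inside the centered
    ``center_size`` square; boxes are translated into patch coordinates and
    kept when at least ``retention`` of their area survives.  When
    ``min_cells``/``max_cells`` are given, patches outside that cell-count
    band are rejected and redrawn (a programmatic stand-in for curating
    patches "with a similar number of cells" by hand), up to a bounded number
    of attempts — fewer than ``count`` patches may be returned for
    infeasible bands.
    """
    h, w = image.height, image.width
    if center_size > min(h, w):
        raise ValueError("center region larger than image")
    if patch_size > center_size:
        raise ValueError("patch larger than center region")
    y0c = (h - center_size) // 2
    x0c = (w - center_size) // 2
    hi = center_size - patch_size
    rng = np.random.default_rng(seed)
    out = []
    attempts = 0
    max_attempts = 20 * count
    while len(out) < count and attempts < max_attempts:
        attempts += 1
        ox = x0c + int(rng.integers(0, hi + 1))
        oy = y0c + int(rng.integers(0, hi + 1))
        boxes = _transfer_boxes(annotation.boxes, -ox, -oy, patch_size, patch_size, retention)
        if min_cells is not None and len(boxes) < min_cells:
            continue
        if max_cells is not None and len(boxes) > max_cells:
            continue
        patch_px = image.pixels[oy:oy + patch_size, ox:ox + patch_size].copy()
        ann = Annotation(f"{annotation.image_id}_p{len(out):03d}",
                         patch_size, patch_size, boxes)
        out.append((RasterImage(patch_px, image.bit_depth), ann))
    return out


def augment(image: RasterImage, annotation: Annotation,
            spec: AugmentationSpec) -> tuple[RasterImage, Annotation]:
    """Apply translation, down-scaling and flips consistently to image and boxes.

    Order: scale, then translate, then horizontal flip, then vertical mirror.
    Scaling resizes the frame itself (a 300 px image at scale 0.5 becomes
    150 px); translated-out content is filled with zeros and boxes falling
    below the retention fraction are dropped.
    """
    px = image.pixels
    boxes = list(annotation.boxes)
    h, w = px.shape[:2]

    if spec.scale != 1.0:
        h2, w2 = int(round(h * spec.scale)), int(round(w * spec.scale))
        px = _sk_resize(px.astype(np.float64), (h2, w2) + px.shape[2:],
                        order=1, anti_aliasing=True, preserve_range=True)
        if not image.is_normalized:
            px = np.round(px).astype(image.pixels.dtype)
        sx, sy = w2 / w, h2 / h
        boxes = [replace(b, xmin=b.xmin * sx, xmax=b.xmax * sx,
                         ymin=b.ymin * sy, ymax=b.ymax * sy) for b in boxes]
        h, w = h2, w2

    dx, dy = int(spec.translate[0]), int(spec.translate[1])
    if dx or dy:
        shifted = np.zeros_like(px)
        src_y = slice(max(0, -dy), min(h, h - dy))
        src_x = slice(max(0, -dx), min(w, w - dx))
        dst_y = slice(max(0, dy), min(h, h + dy))
        dst_x = slice(max(0, dx), min(w, w + dx))
        shifted[dst_y, dst_x] = px[src_y, src_x]
        px = shifted
        boxes = _transfer_boxes(boxes, dx, dy, w, h, spec.retention)

    if spec.hflip:
        px = px[:, ::-1].copy()
        boxes = [replace(b, xmin=w - b.xmax, xmax=w - b.xmin) for b in boxes]
    if spec.mirror:
        px = px[::-1].copy()
        boxes = [replace(b, ymin=h - b.ymax, ymax=h - b.ymin) for b in boxes]

    ann = Annotation(annotation.image_id, int(h), int(w), boxes)
    return RasterImage(px, image.bit_depth), ann
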