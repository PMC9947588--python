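"""Synthetic bright-field spiked-sample image generator.

Emulates the statistical structure of microscopy fields of tumor cells (CTCs)
spiked into a white-blood-cell (WBC) background: sparse large CTC-like cells
(10-20 um) among abundant smaller WBC-like cells (7-12 um) on a bright
background, darker than their surroundings, with intra-cell texture and
additive Gaussian sensor noise.  Every drawn cell gets a tight integer
bounding box, so ground truth is exact by construction.

Cell diameters are drawn from a truncated normal centered on the class range
midpoint (sd = range/6), reflecting that real cell-size distributions cluster
around a typical diameter rather than filling their range uniformly; this
also keeps the two class size distributions nearly disjoint.  Cells are
tilted ellipses rendered exactly tight in their boxes via a correlated
quadratic form, with a radial center-to-rim intensity profile and
multiplicative speckle; CTCs get a darker rim and coarser texture.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
from skimage.transform import resize as _sk_resize

from .imaging_io import (Annotation, BoundingBox, DatasetIndex, RasterImage,
                         write_image, write_voc_annotation)

__all__ = ["SimulationConfig", "CellAppearance", "PlacementError",
           "simulate_image", "simulate_dataset", "simulate_in_memory", "easy_config"]


class PlacementError(RuntimeError):
    """Raised when cells cannot be placed under the overlap rule."""

    def __init__(self, requested: dict, achieved: dict):
        super().__init__(f"placement failed: requested {requested}, achieved {achieved}")
        self.requested = requested
        self.achieved = achieved


@dataclass(frozen=True)
class CellAppearance:
    """Intensity / texture knobs for one cell class (normalized [0,1] scale)."""

    center_level: float     # intensity at the cell center
    rim_level: float        # intensity at the rim (darker rim for CTCs)
    texture_amp: float      # multiplicative speckle amplitude
    texture_scale: int      # speckle correlation length, pixels


@dataclass(frozen=True)
class SimulationConfig:
    image_size: int = 300
    um_per_px: float = 0.62
    n_ctc: int | tuple[int, int] = (1, 3)
    n_wbc: int | tuple[int, int] = (40, 60)
    ctc_diameter_um: tuple[float, float] = (10.0, 20.0)
    wbc_diameter_um: tuple[float, float] = (7.0, 12.0)
    ctc_appearance: CellAppearance = CellAppearance(0.45, 0.22, 0.12, 4)
    wbc_appearance: CellAppearance = CellAppearance(0.58, 0.46, 0.05, 2)
    background_level: float = 0.82
    noise_sigma: float = 0.03
    axis_ratio: tuple[float, float] = (0.7, 1.0)
    max_overlap: float = 0.2     # fraction of the smaller cell's box area
    max_retries: int = 200
    bit_depth: int = 8
    seed: int = 0

    def __post_init__(self):
        for rng_ in (self.ctc_diameter_um, self.wbc_diameter_um):
            if rng_[0] <= 0 or rng_[1] <= rng_[0]:
                raise ValueError("diameter ranges must be positive and increasing")
        mid = lambda r: 0.5 * (r[0] + r[1])
        if mid(self.ctc_diameter_um) <= mid(self.wbc_diameter_um):
            raise ValueError("CTC diameter midpoint must exceed the WBC midpoint")
        largest_px = self.ctc_diameter_um[1] / self.um_per_px
        if self.image_size <= largest_px:
            raise ValueError("image smaller than the largest cell")


def easy_config(seed: int = 0, image_size: int = 150) -> SimulationConfig:
    """High-contrast, non-overlapping preset used for desk-scale training."""
    return SimulationConfig(
        image_size=image_size,
        n_ctc=(1, 2),
        n_wbc=(8, 15),
        ctc_appearance=CellAppearance(0.35, 0.15, 0.10, 4),
        wbc_appearance=CellAppearance(0.60, 0.50, 0.04, 2),
        noise_sigma=0.02,
        max_overlap=0.0,
        seed=seed,
    )


def _draw_count(rng: np.random.Generator, spec: int | tuple[int, int]) -> int:
    if isinstance(spec, tuple):
        return int(rng.integers(spec[0], spec[1] + 1))
    return int(spec)


def _sample_diameter_px(rng: np.random.Generator, um_range: tuple[float, float],
                        um_per_px: float) -> int:
    """Integer pixel diameter whose micron equivalent stays inside the range."""
    lo, hi = um_range
    mu, sd = 0.5 * (lo + hi), (hi - lo) / 6.0
    d_um = float(np.clip(rng.normal(mu, sd), lo, hi))
    n_lo = int(np.ceil(lo / um_per_px))
    n_hi = int(np.floor(hi / um_per_px))
    return int(np.clip(round(d_um / um_per_px), n_lo, n_hi))


def _box_overlap(a: tuple, b: tuple) -> float:
    ix = max(0.0, min(a[2], b[2]) - max(a[0], b[0]))
    iy = max(0.0, min(a[3], b[3]) - max(a[1], b[1]))
    return ix * iy


def _render_cell(img: np.ndarray, rng: np.random.Generator, box: tuple[int, int, int, int],
                 rho: float, look: CellAppearance):
    x0, y0, x1, y1 = box
    wx, wy = x1 - x0, y1 - y0
    ex, ey = wx / 2.0, wy / 2.0
    cx, cy = x0 + ex, y0 + ey
    # tilted ellipse exactly tight in its box: quadratic form with covariance
    # [[ex^2, rho*ex*ey], [rho*ex*ey, ey^2]] has half-extents (ex, ey)
    det = (ex * ey) ** 2 * (1.0 - rho * rho)
    q11 = ey * ey / det
    q22 = ex * ex / det
    q12 = -rho * ex * ey / det
    ys, xs = np.mgrid[y0:y1, x0:x1]
    u = xs + 0.5 - cx
    v = ys + 0.5 - cy
    rn = np.sqrt(np.maximum(q11 * u * u + 2 * q12 * u * v + q22 * v * v, 0.0))
    alpha = np.clip((1.0 - rn) * min(ex, ey) / 0.75, 0.0, 1.0)
    t = np.clip(rn, 0.0, 1.0) ** 2
    level = look.center_level * (1.0 - t) + look.rim_level * t
    if look.texture_amp > 0:
        g = max(2, int(np.ceil(wx / look.texture_scale))), \
            max(2, int(np.ceil(wy / look.texture_scale)))
        speck = rng.normal(0.0, 1.0, size=(g[1], g[0]))
        speck = _sk_resize(speck, (wy, wx), order=1, anti_aliasing=False)
        level = level * (1.0 + look.texture_amp * np.clip(speck, -2.5, 2.5))
    patch = img[y0:y1, x0:x1]
    img[y0:y1, x0:x1] = patch * (1.0 - alpha) + level * alpha


def simulate_image(config: SimulationConfig) -> tuple[RasterImage, Annotation]:
    """Render one annotated field; deterministic for a fixed ``config.seed``."""
    rng = np.random.default_rng(config.seed)
    size = config.image_size
    requested = {"CTC": _draw_count(rng, config.n_ctc),
                 "WBC": _draw_count(rng, config.n_wbc)}
    placed: list[tuple[tuple, str, float]] = []  # (box, label, rho)
    for label, dia_range, _look in (("CTC", config.ctc_diameter_um, config.ctc_appearance),
                                    ("WBC", config.wbc_diameter_um, config.wbc_appearance)):
        for _ in range(requested[label]):
            ok = False
            for _try in range(config.max_retries):
                n = _sample_diameter_px(rng, dia_range, config.um_per_px)
                q = float(rng.uniform(*config.axis_ratio))
                minor = max(3, int(round(n * q)))
                wx, wy = (n, minor) if rng.random() < 0.5 else (minor, n)
                x0 = int(rng.integers(1, size - wx))
                y0 = int(rng.integers(1, size - wy))
                box = (x0, y0, x0 + wx, y0 + wy)
                area = wx * wy
                clash = False
                for other, _, _ in placed:
                    oa = (other[2] - other[0]) * (other[3] - other[1])
                    if _box_overlap(box, other) > config.max_overlap * min(area, oa):
                        clash = True
                        break
                if not clash:
                    rho = float(rng.uniform(-0.4, 0.4))
                    placed.append((box, label, rho))
                    ok = True
                    break
            if not ok:
                achieved = {c: sum(1 for _, lb, _ in placed if lb == c) for c in ("CTC", "WBC")}
                raise PlacementError(requested, achieved)

    img = np.full((size, size), config.background_level, dtype=np.float64)
    look = {"CTC": config.ctc_appearance, "WBC": config.wbc_appearance}
    for box, label, rho in placed:
        _render_cell(img, rng, box, rho, look[label])
    if config.noise_sigma > 0:
        img += rng.normal(0.0, config.noise_sigma, size=img.shape)
    img = np.clip(img, 0.0, 1.0)

    boxes = [BoundingBox(*box, label=label) for box, label, _ in placed]
    ann = Annotation(f"sim{config.seed:08d}", size, size, boxes)
    raster = RasterImage(img, bit_depth=config.bit_depth).to_raw()
    return raster, ann


def _child_seed(seed: int, i: int) -> int:
    return int(np.random.SeedSequence([seed, i]).generate_state(1)[0] % (2 ** 31))


def simulate_dataset(config: SimulationConfig, n_images: int,
                     out_dir: str | Path) -> DatasetIndex:
    """Write ``n_images`` PNG + VOC-XML pairs and return an index over them."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    records = []
    for i in range(n_images):
        cfg = replace(config, seed=_child_seed(config.seed, i))
        raster, ann = simulate_image(cfg)
        ann.image_id = f"img_{i:05d}"
        img_path = out_dir / f"img_{i:05d}.png"
        xml_path = out_dir / f"img_{i:05d}.xml"
        write_image(raster, img_path)
        write_voc_annotation(ann, xml_path, image_filename=img_path.name)
        records.append((str(img_path), str(xml_path)))
    return DatasetIndex(records, seed=config.seed)


def simulate_in_memory(config: SimulationConfig,
                       n_images: int) -> list[tuple[RasterImage, Annotation]]:
    """Like :func:`simulate_dataset` but without touching the filesystem."""
    out = []
    for i in range(n_images):
        cfg = replace(config, seed=_child_seed(config.seed, i))
        raster, ann = simulate_image(cfg)
        ann.image_id = f"img_{i:05d}"
        out.append((raster, ann))
    return out
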