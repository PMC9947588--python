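"""Image and annotation I/O for bright-field cell-detection datasets.

Images are 8- or 16-bit grayscale (or 8-bit RGB) PNG/TIFF files; annotations
are a Pascal-VOC-style XML subset with two object classes, ``CTC`` and
``WBC``.  Boxes are held internally in a 0-based, half-open pixel convention
``[xmin, xmax) x [ymin, ymax)`` so that ``width = xmax - xmin``; VOC's 1-based
inclusive coordinates are converted at the file boundary.
"""

from __future__ import annotations

import xml.etree.ElementTree as ET
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
from PIL import Image as PILImage

try:  # tifffile preserves 16-bit TIFF exactly
    import tifffile
except ImportError:  # pragma: no cover
    tifffile = None

CLASSES = ("CTC", "WBC")

__all__ = [
    "CLASSES", "RasterImage", "BoundingBox", "Annotation", "DatasetIndex",
    "read_image", "write_image", "read_voc_annotation", "write_voc_annotation",
    "make_splits", "write_manifest", "read_manifest",
]


class FormatError(ValueError):
    """Unsupported or malformed file content."""


class LabelError(ValueError):
    """Unknown object class name in an annotation."""


@dataclass
class RasterImage:
    """Pixel raster plus bit-depth metadata.

    ``pixels`` holds raw integer intensities (uint8/uint16) or, after
    :meth:`normalized`, floats in [0, 1].  Shape is (H, W) or (H, W, 3).
    """

    pixels: np.ndarray
    bit_depth: int = 8

    def __post_init__(self):
        if self.pixels.ndim not in (2, 3):
            raise ValueError("pixels must be 2-D or 3-channel")
        if self.bit_depth not in (8, 16):
            raise ValueError("bit_depth must be 8 or 16")

    @property
    def height(self) -> int:
        return self.pixels.shape[0]

    @property
    def width(self) -> int:
        return self.pixels.shape[1]

    @property
    def is_normalized(self) -> bool:
        return np.issubdtype(self.pixels.dtype, np.floating)

    def normalized(self) -> "RasterImage":
        """Linearly rescale raw intensities to floats in [0, 1]."""
        if self.is_normalized:
            return self
        scale = float(2 ** self.bit_depth - 1)
        return RasterImage(self.pixels.astype(np.float64) / scale, self.bit_depth)

    def to_raw(self) -> "RasterImage":
        if not self.is_normalized:
            return self
        scale = 2 ** self.bit_depth - 1
        dtype = np.uint8 if self.bit_depth == 8 else np.uint16
        raw = np.round(np.clip(self.pixels, 0.0, 1.0) * scale).astype(dtype)
        return RasterImage(raw, self.bit_depth)

    def gray(self) -> np.ndarray:
        """Single-channel view (mean over channels for RGB)."""
        if self.pixels.ndim == 2:
            return self.pixels
        return self.pixels.mean(axis=2)


@dataclass(frozen=True)
class BoundingBox:
    """Half-open pixel box [xmin, xmax) x [ymin, ymax), 0-based."""

    xmin: float
    ymin: float
    xmax: float
    ymax: float
    label: str = "CTC"
    score: float | None = None

    def __post_init__(self):
        if not (self.xmin < self.xmax and self.ymin < self.ymax):
            raise ValueError(f"degenerate box {(self.xmin, self.ymin, self.xmax, self.ymax)}")

    @property
    def width(self) -> float:
        return self.xmax - self.xmin

    @property
    def height(self) -> float:
        return self.ymax - self.ymin

    @property
    def area(self) -> float:
        return self.width * self.height

    def shifted(self, dx: float, dy: float) -> "BoundingBox":
        return replace(self, xmin=self.xmin + dx, xmax=self.xmax + dx,
                       ymin=self.ymin + dy, ymax=self.ymax + dy)

    def clipped(self, width: float, height: float) -> "BoundingBox | None":
        x0, y0 = max(self.xmin, 0.0), max(self.ymin, 0.0)
        x1, y1 = min(self.xmax, width), min(self.ymax, height)
        if x0 >= x1 or y0 >= y1:
            return None
        return replace(self, xmin=x0, ymin=y0, xmax=x1, ymax=y1)


@dataclass
class Annotation:
    image_id: str
    height: int
    width: int
    boxes: list[BoundingBox] = field(default_factory=list)

    def of_class(self, label: str) -> list[BoundingBox]:
        return [b for b in self.boxes if b.label == label]


@dataclass
class DatasetIndex:
    """Records of (image path, annotation path) with optional split labels."""

    records: list[tuple[str, str]]
    splits: dict[str, list[int]] = field(default_factory=dict)
    seed: int | None = None

    def paths(self, split: str | None = None) -> list[tuple[str, str]]:
        if split is None:
            return list(self.records)
        return [self.records[i] for i in self.splits[split]]

    def __len__(self) -> int:
        return len(self.records)


# ---------------------------------------------------------------------------
# images
# ---------------------------------------------------------------------------

def read_image(path: str | Path) -> RasterImage:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    suffix = path.suffix.lower()
    if suffix in (".tif", ".tiff"):
        arr = tifffile.imread(path)
    elif suffix == ".png":
        arr = np.asarray(PILImage.open(path))
    else:
        raise FormatError(f"unsupported image format: {path.suffix}")
    if arr.ndim == 3 and arr.shape[2] == 4:  # drop alpha
        arr = arr[:, :, :3]
    if arr.dtype == np.uint8:
        depth = 8
    elif arr.dtype == np.uint16:
        depth = 16
    elif arr.dtype == np.int32:  # PIL mode "I" for 16-bit PNG
        arr = arr.astype(np.uint16)
        depth = 16
    else:
        raise FormatError(f"unsupported pixel dtype {arr.dtype} in {path}")
    return RasterImage(np.ascontiguousarray(arr), depth)


def write_image(image: RasterImage, path: str | Path):
    path = Path(path)
    raw = image.to_raw()
    suffix = path.suffix.lower()
    if suffix in (".tif", ".tiff"):
        tifffile.imwrite(path, raw.pixels)
    elif suffix == ".png":
        if raw.bit_depth == 16:
            if raw.pixels.ndim != 2:
                raise FormatError("16-bit PNG supported for grayscale only")
            PILImage.fromarray(raw.pixels.astype(np.uint16)).save(path)
        else:
            PILImage.fromarray(raw.pixels).save(path)
    else:
        raise FormatError(f"unsupported image format: {path.suffix}")


# ---------------------------------------------------------------------------
# VOC XML
# ---------------------------------------------------------------------------

def read_voc_annotation(path: str | Path) -> Annotation:
    path = Path(path)
    try:
        root = ET.parse(path).getroot()
    except ET.ParseError as e:
        raise FormatError(f"malformed XML in {path}: {e}") from e
    size = root.find("size")
    height = int(size.findtext("height"))
    width = int(size.findtext("width"))
    image_id = root.findtext("filename", default=path.stem)
    image_id = Path(image_id).stem
    boxes = []
    for obj in root.iter("object"):
        name = obj.findtext("name")
        if name not in CLASSES:
            raise LabelError(f"unknown class name {name!r} in {path}")
        bb = obj.find("bndbox")
        # VOC is 1-based inclusive; convert to 0-based half-open
        xmin = int(bb.findtext("xmin")) - 1
        ymin = int(bb.findtext("ymin")) - 1
        xmax = int(bb.findtext("xmax"))
        ymax = int(bb.findtext("ymax"))
        boxes.append(BoundingBox(xmin, ymin, xmax, ymax, label=name))
    return Annotation(image_id, height, width, boxes)


def write_voc_annotation(annotation: Annotation, path: str | Path,
                         image_filename: str | None = None):
    root = ET.Element("annotation")
    ET.SubElement(root, "folder").text = "images"
    ET.SubElement(root, "filename").text = image_filename or f"{annotation.image_id}.png"
    size = ET.SubElement(root, "size")
    ET.SubElement(size, "width").text = str(annotation.width)
    ET.SubElement(size, "height").text = str(annotation.height)
    ET.SubElement(size, "depth").text = "1"
    for box in annotation.boxes:
        obj = ET.SubElement(root, "object")
        ET.SubElement(obj, "name").text = box.label
        ET.SubElement(obj, "difficult").text = "0"
        bb = ET.SubElement(obj, "bndbox")
        ET.SubElement(bb, "xmin").text = str(int(round(box.xmin)) + 1)
        ET.SubElement(bb, "ymin").text = str(int(round(box.ymin)) + 1)
        ET.SubElement(bb, "xmax").text = str(int(round(box.xmax)))
        ET.SubElement(bb, "ymax").text = str(int(round(box.ymax)))
    tree = ET.ElementTree(root)
    ET.indent(tree)
    tree.write(path, encoding="unicode", xml_declaration=True)


# ---------------------------------------------------------------------------
# dataset index / splits
# ---------------------------------------------------------------------------

def make_splits(index: DatasetIndex, fractions: tuple[float, float, float] = (0.8, 0.1, 0.1),
                seed: int = 0) -> DatasetIndex:
    """Assign records to train/val/test by shuffling with ``seed``.

    Split sizes are the rounded fractions of the record count (train takes the
    remainder so the partition is exhaustive).
    """
    fr = np.asarray(fractions, dtype=float)
    if np.any(fr < 0) or abs(fr.sum() - 1.0) > 1e-9:
        raise ValueError("fractions must be nonnegative and sum to 1")
    n = len(index.records)
    n_nonzero = int(np.count_nonzero(fr))
    if n < n_nonzero:
        raise ValueError(f"{n} records cannot populate {n_nonzero} nonempty splits")
    n_val = int(round(fr[1] * n))
    n_test = int(round(fr[2] * n))
    n_train = n - n_val - n_test
    if (n_train == 0) != (fr[0] == 0):
        raise ValueError("rounding produced an empty train split")
    order = np.random.default_rng(seed).permutation(n)
    splits = {
        "train": sorted(int(i) for i in order[:n_train]),
        "val": sorted(int(i) for i in order[n_train:n_train + n_val]),
        "test": sorted(int(i) for i in order[n_train + n_val:]),
    }
    return DatasetIndex(list(index.records), splits, seed=seed)


def write_manifest(index: DatasetIndex, path: str | Path):
    """One ``image_path<TAB>xml_path`` per line."""
    lines = [f"{img}\t{xml}" for img, xml in index.records]
    Path(path).write_text("\n".join(lines) + "\n")


def read_manifest(path: str | Path) -> DatasetIndex:
    records = []
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if not line:
            continue
        img, xml = line.split("\t")
        records.append((img, xml))
    return DatasetIndex(records)
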