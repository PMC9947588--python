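"""SSD-style multi-scale cell detector with CBAM attention and feature fusion.

The network is a VGG16-style backbone (13 convolutions in five blocks, then
two convolutionalized fully-connected layers) feeding six detection feature
maps of strictly decreasing grid size.  Convolutional block attention (CBAM:
channel gating from pooled descriptors through a shared MLP, then spatial
gating from pooled channel maps through a 7x7 convolution) is applied to the
first four feature maps; transpose-convolution feature fusion upsamples each
of the three higher-level maps into the map below it, concatenates, and
projects back with a 1x1 convolution.  Both additions are strictly optional:
with attention and fusion disabled the forward pass is a plain SSD.

Default boxes ("anchors") follow the SSD convention: per feature map, a
square box at the layer size, a square box at the geometric mean of this and
the next layer size, and aspect-ratio variants {2, 1/2} (+{3, 1/3} on
6-anchor layers).  The size list defaults to [21, 45, 99, 153, 207, 261, 315]
pixels on a 300-pixel input and scales linearly with input size.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from . import autodiff as ad
from . import nn
from .autodiff import Tensor
from .imaging_io import BoundingBox, RasterImage

__all__ = [
    "NetworkConfig", "AnchorSet", "DetectionResult", "ConfigurationError",
    "desk_config", "feature_plan", "generate_anchors",
    "CBAM", "FusionBlock", "SSDDetector", "build_detector",
    "encode_boxes", "decode_boxes", "nms", "decode_and_filter",
    "save_checkpoint", "load_checkpoint", "prepare_input",
]

ANCHORS_PER_LOC = (4, 6, 6, 6, 4, 4)
DEFAULT_ANCHOR_SIZES = (21.0, 45.0, 99.0, 153.0, 207.0, 261.0, 315.0)


class ConfigurationError(ValueError):
    pass


@dataclass(frozen=True)
class NetworkConfig:
    input_size: int = 300
    width: float = 1.0               # backbone width multiplier
    n_classes: int = 3               # background + CTC + WBC
    in_channels: int = 3
    attention: bool = True
    fusion: bool = True
    cbam_reduction: int = 8
    anchor_sizes: tuple = DEFAULT_ANCHOR_SIZES   # pixels on a 300-px input
    variances: tuple = (0.1, 0.1, 0.2, 0.2)
    score_threshold: float = 0.5
    nms_threshold: float = 0.5

    def __post_init__(self):
        if not (0.0 < self.width <= 1.0):
            raise ConfigurationError("width multiplier must lie in (0, 1]")

    def channels(self, base: int) -> int:
        return max(8, int(round(base * self.width)))


def desk_config(**overrides) -> NetworkConfig:
    """CPU-trainable profile: quarter-width backbone on 150-pixel inputs."""
    kwargs = dict(input_size=150, width=0.25)
    kwargs.update(overrides)
    return NetworkConfig(**kwargs)


# ---------------------------------------------------------------------------
# feature-map geometry
# ---------------------------------------------------------------------------

def _ceil_half(g: int) -> int:
    return (g + 1) // 2


def _plan_extras(g: int, steps: int = 4) -> list[tuple[int, int, int, int]]:
    """Plan (kernel, stride, pad, out_grid) for the extra layers down to grid 1."""

    def moves(cur):
        out = []
        if cur >= 3:
            out.append((3, 2, 1, _ceil_half(cur)))
            out.append((3, 1, 0, cur - 2))
        if cur == 2:
            out.append((2, 1, 0, 1))
        return out

    def dfs(cur, left):
        if left == 0:
            return [] if cur == 1 else None
        for mv in moves(cur):
            if mv[3] < 1:
                continue
            rest = dfs(mv[3], left - 1)
            if rest is not None:
                return [mv] + rest
        return None

    plan = dfs(g, steps)
    if plan is None:
        raise ConfigurationError(f"cannot plan {steps} extra layers from grid {g}")
    return plan


def feature_plan(input_size: int) -> tuple[list[int], list[tuple[int, int, int, int]]]:
    """Grid sizes of the six feature maps, plus the extra-layer conv plan."""
    g = input_size
    for _ in range(3):
        g = _ceil_half(g)
    f1 = g
    f2 = _ceil_half(g)
    extras = _plan_extras(f2)
    grids = [f1, f2] + [mv[3] for mv in extras]
    if len(set(grids)) != 6 or any(a <= b for a, b in zip(grids, grids[1:])):
        raise ConfigurationError(f"degenerate feature grids {grids} for input {input_size}")
    return grids, extras


# ---------------------------------------------------------------------------
# anchors
# ---------------------------------------------------------------------------

@dataclass
class AnchorSet:
    """All default boxes across scales, as (cx, cy, w, h) in input pixels."""

    boxes: np.ndarray                 # (A, 4) cx, cy, w, h
    layer_of_origin: np.ndarray       # (A,)
    sizes: tuple
    grids: list[int]
    anchors_per_loc: tuple
    input_size: int

    def __len__(self) -> int:
        return self.boxes.shape[0]

    def as_corners(self) -> np.ndarray:
        b = self.boxes
        half = b[:, 2:] / 2.0
        return np.concatenate([b[:, :2] - half, b[:, :2] + half], axis=1)


def expected_anchor_count(grids, anchors_per_loc=ANCHORS_PER_LOC) -> int:
    return int(sum(a * g * g for g, a in zip(grids, anchors_per_loc)))


def generate_anchors(config: NetworkConfig) -> AnchorSet:
    grids, _ = feature_plan(config.input_size)
    sizes = tuple(s * config.input_size / 300.0 for s in config.anchor_sizes)
    if len(sizes) != len(grids) + 1:
        raise ConfigurationError(
            f"need {len(grids) + 1} anchor sizes for {len(grids)} layers, got {len(sizes)}")
    rows = []
    origin = []
    for layer, (g, n_anchor) in enumerate(zip(grids, ANCHORS_PER_LOC)):
        s = sizes[layer]
        s_prime = math.sqrt(sizes[layer] * sizes[layer + 1])
        shapes = [(s, s), (s_prime, s_prime),
                  (s * math.sqrt(2.0), s / math.sqrt(2.0)),
                  (s / math.sqrt(2.0), s * math.sqrt(2.0))]
        if n_anchor == 6:
            shapes += [(s * math.sqrt(3.0), s / math.sqrt(3.0)),
                       (s / math.sqrt(3.0), s * math.sqrt(3.0))]
        step = config.input_size / g
        for i in range(g):
            cy = (i + 0.5) * step
            for j in range(g):
                cx = (j + 0.5) * step
                for (w, h) in shapes:
                    rows.append((cx, cy, w, h))
                    origin.append(layer)
    return AnchorSet(np.asarray(rows, dtype=np.float32),
                     np.asarray(origin, dtype=np.int32),
                     sizes, grids, ANCHORS_PER_LOC, config.input_size)


# ---------------------------------------------------------------------------
# modules
# ---------------------------------------------------------------------------

class CBAM(nn.Module):
    """Convolutional block attention: channel gate then spatial gate."""

    def __init__(self, channels: int, reduction: int, rng: np.random.Generator):
        if channels % reduction:
            raise ConfigurationError(f"{channels} channels not divisible by r={reduction}")
        hidden = channels // reduction
        self.fc1 = nn.Linear(channels, hidden, rng=rng)
        self.fc2 = nn.Linear(hidden, channels, rng=rng)
        self.spatial = nn.Conv2d(2, 1, 7, pad=3, rng=rng)

    def forward(self, x: Tensor) -> Tensor:
        n, c, h, w = x.shape
        avg = ad.tmean(x, axis=(2, 3))                       # (N, C)
        mx = ad.amax(ad.amax(x, axis=3, keepdims=False), axis=2, keepdims=False)
        shared = lambda v: self.fc2(ad.relu(self.fc1(v)))
        gate_c = ad.sigmoid(ad.add(shared(avg), shared(mx)))
        x = ad.mul(x, ad.reshape(gate_c, (n, c, 1, 1)))
        cmax = ad.amax(x, axis=1, keepdims=True)
        cmean = ad.tmean(x, axis=1, keepdims=True)
        gate_s = ad.sigmoid(self.spatial(ad.concat([cmax, cmean], axis=1)))
        return ad.mul(x, gate_s)


def _plan_upsample(g_high: int, g_low: int) -> tuple[int, int, int]:
    """(kernel, stride, pad) for a stride-2 transpose conv mapping g_high -> g_low."""
    delta = g_low - 2 * (g_high - 1)   # = k - 2p
    for k in (2, 3, 4):
        if (k - delta) >= 0 and (k - delta) % 2 == 0:
            return k, 2, (k - delta) // 2
    raise ConfigurationError(f"no stride-2 transpose conv maps grid {g_high} to {g_low}")


class FusionBlock(nn.Module):
    """Upsample a high-level map, concatenate with the low-level map, project 1x1."""

    def __init__(self, c_high: int, c_low: int, g_high: int, g_low: int,
                 rng: np.random.Generator):
        k, s, p = _plan_upsample(g_high, g_low)
        self.up = nn.ConvTranspose2d(c_high, c_high, k, stride=s, pad=p, rng=rng)
        self.proj = nn.Conv2d(c_high + c_low, c_low, 1, rng=rng)

    def forward(self, high: Tensor, low: Tensor) -> Tensor:
        u = self.up(high)
        if u.shape[2:] != low.shape[2:]:
            raise ConfigurationError(f"fusion grids mismatch: {u.shape} vs {low.shape}")
        return ad.relu(self.proj(ad.concat([u, low], axis=1)))


class _ConvRelu(nn.Module):
    def __init__(self, cin, cout, k, stride=1, pad=0, rng=None):
        self.conv = nn.Conv2d(cin, cout, k, stride=stride, pad=pad, rng=rng)

    def forward(self, x):
        return ad.relu(self.conv(x))


class SSDDetector(nn.Module):
    """Six-scale single-shot detector; see the module docstring for wiring."""

    #: parameter-name prefixes that belong to the feature-extraction backbone
    BACKBONE_PREFIXES = ("blocks", "fc")

    def __init__(self, config: NetworkConfig, rng: np.random.Generator):
        self.config = config
        grids, extras_plan = feature_plan(config.input_size)
        self.grids = grids
        ch = config.channels
        c = [ch(64), ch(128), ch(256), ch(512), ch(512)]
        cf = ch(1024)

        def conv(cin, cout, k=3, stride=1, pad=1):
            return _ConvRelu(cin, cout, k, stride=stride, pad=pad, rng=rng)

        self.blocks = [
            [conv(config.in_channels, c[0]), conv(c[0], c[0])],
            [conv(c[0], c[1]), conv(c[1], c[1])],
            [conv(c[1], c[2]), conv(c[2], c[2]), conv(c[2], c[2])],
            [conv(c[2], c[3]), conv(c[3], c[3]), conv(c[3], c[3])],
            [conv(c[3], c[4]), conv(c[4], c[4]), conv(c[4], c[4])],
        ]
        self.fc = [conv(c[4], cf), conv(cf, cf, k=1, pad=0)]

        extra_ch = [(ch(256), ch(512)), (ch(128), ch(256)),
                    (ch(128), ch(256)), (ch(128), ch(256))]
        self.extras = []
        cin = cf
        for (cmid, cout), (k, s, p, _g) in zip(extra_ch, extras_plan):
            self.extras.append([conv(cin, cmid, k=1, pad=0), conv(cmid, cout, k=k, stride=s, pad=p)])
            cin = cout
        self.feature_channels = [c[3], cf] + [co for _, co in extra_ch]

        if config.attention:
            self.cbam = [CBAM(self.feature_channels[i], config.cbam_reduction, rng)
                         for i in range(4)]
        else:
            self.cbam = []
        if config.fusion:
            self.fusions = [FusionBlock(self.feature_channels[l + 1],
                                        self.feature_channels[l],
                                        grids[l + 1], grids[l], rng)
                            for l in range(3)]
        else:
            self.fusions = []

        self.cls_heads = [nn.Conv2d(cl, a * config.n_classes, 3, pad=1, rng=rng)
                          for cl, a in zip(self.feature_channels, ANCHORS_PER_LOC)]
        self.loc_heads = [nn.Conv2d(cl, a * 4, 3, pad=1, rng=rng)
                          for cl, a in zip(self.feature_channels, ANCHORS_PER_LOC)]

    def load_backbone(self, state: dict[str, np.ndarray]):
        """Import externally trained backbone weights (``blocks.*`` / ``fc.*``).

        Entries for other parameter groups are ignored; shapes must match the
        configured architecture exactly.  Never required — the detector trains
        from scratch by default.
        """
        own = {k: p for k, p in self.named_parameters()
               if k.startswith(self.BACKBONE_PREFIXES)}
        loaded = 0
        for name, arr in state.items():
            if name in own:
                arr = np.asarray(arr, dtype=own[name].data.dtype)
                if arr.shape != own[name].data.shape:
                    raise ValueError(f"backbone shape mismatch for {name}")
                own[name].data = arr.copy()
                loaded += 1
        if loaded == 0:
            raise ValueError("no backbone parameters found in the given state")
        return loaded

    # -- forward -------------------------------------------------------
    def backbone_features(self, x: Tensor) -> list[Tensor]:
        feats = []
        for bi, block in enumerate(self.blocks):
            for layer in block:
                x = layer(x)
            if bi == 3:
                feats.append(x)            # feature 1 (before the 4th pool)
            if bi < 4:
                x = ad.maxpool2d(x, 2, ceil_mode=True)
        for layer in self.fc:
            x = layer(x)
        feats.append(x)                    # feature 2
        for extra in self.extras:
            for layer in extra:
                x = layer(x)
            feats.append(x)
        return feats

    def forward(self, x: np.ndarray | Tensor) -> tuple[Tensor, Tensor, list[Tensor]]:
        """Returns (class scores (N, A, K), box offsets (N, A, 4), feature maps).

        The returned feature maps are the attended multi-level maps *before*
        fusion — the six per-layer maps class-activation mapping visualizes;
        the detection heads consume the fused maps.  With attention and
        fusion disabled these are the raw per-scale maps of a plain SSD.
        """
        if not isinstance(x, Tensor):
            x = Tensor(np.ascontiguousarray(x, dtype=np.float32))
        if x.shape[2] != self.config.input_size or x.shape[3] != self.config.input_size:
            raise ValueError(f"input must be {self.config.input_size} px, got {x.shape}")
        feats = self.backbone_features(x)
        if self.config.attention:
            for i in range(4):
                feats[i] = self.cbam[i](feats[i])
        interp_feats = list(feats)         # attended, pre-fusion: one per scale
        if self.config.fusion:
            highs = list(feats)            # fuse in parallel from the attended maps
            for l in range(3):
                feats[l] = self.fusions[l](highs[l + 1], feats[l])
        n = x.shape[0]
        k = self.config.n_classes
        conf_parts, loc_parts = [], []
        for f, ch_, lh, a in zip(feats, self.cls_heads, self.loc_heads, ANCHORS_PER_LOC):
            g = f.shape[2]
            cp = ad.reshape(ad.transpose(ch_(f), (0, 2, 3, 1)), (n, g * g * a, k))
            lp = ad.reshape(ad.transpose(lh(f), (0, 2, 3, 1)), (n, g * g * a, 4))
            conf_parts.append(cp)
            loc_parts.append(lp)
        return ad.concat(conf_parts, axis=1), ad.concat(loc_parts, axis=1), interp_feats


def build_detector(config: NetworkConfig, seed: int = 0) -> SSDDetector:
    return SSDDetector(config, np.random.default_rng(seed))


# ---------------------------------------------------------------------------
# box encoding / decoding / suppression
# ---------------------------------------------------------------------------

def _corners_to_cxcywh(boxes: np.ndarray) -> np.ndarray:
    wh = boxes[:, 2:] - boxes[:, :2]
    return np.concatenate([boxes[:, :2] + wh / 2.0, wh], axis=1)


def encode_boxes(boxes_corners: np.ndarray, anchors_cxcywh: np.ndarray,
                 variances=(0.1, 0.1, 0.2, 0.2)) -> np.ndarray:
    """Center-offset / log-size encoding of corner boxes against anchors."""
    b = _corners_to_cxcywh(np.asarray(boxes_corners, dtype=np.float64))
    a = np.asarray(anchors_cxcywh, dtype=np.float64)
    t = np.empty_like(b)
    t[:, 0] = (b[:, 0] - a[:, 0]) / (a[:, 2] * variances[0])
    t[:, 1] = (b[:, 1] - a[:, 1]) / (a[:, 3] * variances[1])
    t[:, 2] = np.log(b[:, 2] / a[:, 2]) / variances[2]
    t[:, 3] = np.log(b[:, 3] / a[:, 3]) / variances[3]
    return t


def decode_boxes(offsets: np.ndarray, anchors_cxcywh: np.ndarray,
                 variances=(0.1, 0.1, 0.2, 0.2)) -> np.ndarray:
    """Inverse of :func:`encode_boxes`; returns corner boxes."""
    t = np.asarray(offsets, dtype=np.float64)
    a = np.asarray(anchors_cxcywh, dtype=np.float64)
    cx = t[:, 0] * variances[0] * a[:, 2] + a[:, 0]
    cy = t[:, 1] * variances[1] * a[:, 3] + a[:, 1]
    w = np.exp(t[:, 2] * variances[2]) * a[:, 2]
    h = np.exp(t[:, 3] * variances[3]) * a[:, 3]
    return np.stack([cx - w / 2, cy - h / 2, cx + w / 2, cy + h / 2], axis=1)


def _iou_matrix(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Pairwise IOU between corner boxes (M, 4) x (N, 4)."""
    a = np.asarray(a, dtype=np.float64)
    b = np.asarray(b, dtype=np.float64)
    ix = np.clip(np.minimum(a[:, None, 2], b[None, :, 2])
                 - np.maximum(a[:, None, 0], b[None, :, 0]), 0, None)
    iy = np.clip(np.minimum(a[:, None, 3], b[None, :, 3])
                 - np.maximum(a[:, None, 1], b[None, :, 1]), 0, None)
    inter = ix * iy
    area_a = (a[:, 2] - a[:, 0]) * (a[:, 3] - a[:, 1])
    area_b = (b[:, 2] - b[:, 0]) * (b[:, 3] - b[:, 1])
    union = area_a[:, None] + area_b[None, :] - inter
    return np.where(union > 0, inter / union, 0.0)


def nms(boxes: np.ndarray, scores: np.ndarray, iou_threshold: float = 0.5) -> list[int]:
    """Greedy non-maximum suppression; returns kept indices, best first."""
    order = np.argsort(-np.asarray(scores), kind="stable")
    boxes = np.asarray(boxes, dtype=np.float64)
    kept: list[int] = []
    suppressed = np.zeros(len(order), dtype=bool)
    for oi, idx in enumerate(order):
        if suppressed[oi]:
            continue
        kept.append(int(idx))
        rest = order[oi + 1:]
        if len(rest) == 0:
            break
        ious = _iou_matrix(boxes[idx:idx + 1], boxes[rest])[0]
        suppressed[oi + 1:] |= ious > iou_threshold
    return kept


@dataclass
class DetectionResult:
    """Decoded, thresholded, NMS-filtered detections for one image."""

    image_id: str
    boxes: list[BoundingBox]
    anchor_indices: list[int] = field(default_factory=list)
    class_indices: list[int] = field(default_factory=list)


def decode_and_filter(conf: np.ndarray, loc: np.ndarray, anchors: AnchorSet,
                      config: NetworkConfig, image_id: str = "",
                      score_threshold: float | None = None,
                      nms_threshold: float | None = None,
                      class_names: tuple = ("CTC", "WBC")) -> DetectionResult:
    """Turn raw per-anchor predictions into scored, suppressed boxes."""
    score_thr = config.score_threshold if score_threshold is None else score_threshold
    nms_thr = config.nms_threshold if nms_threshold is None else nms_threshold
    conf = np.asarray(conf, dtype=np.float64)
    loc = np.asarray(loc, dtype=np.float64)
    z = conf - conf.max(axis=1, keepdims=True)
    probs = np.exp(z)
    probs /= probs.sum(axis=1, keepdims=True)
    decoded = decode_boxes(loc, anchors.boxes, config.variances)
    size = float(config.input_size)
    out_boxes, out_anchors, out_classes = [], [], []
    for ci, name in enumerate(class_names, start=1):
        scores = probs[:, ci]
        cand = np.nonzero(scores >= score_thr)[0]
        if cand.size == 0:
            continue
        keep = nms(decoded[cand], scores[cand], nms_thr)
        for k in keep:
            ai = int(cand[k])
            x0, y0, x1, y1 = decoded[ai]
            x0, y0 = max(0.0, x0), max(0.0, y0)
            x1, y1 = min(size, x1), min(size, y1)
            if x1 <= x0 or y1 <= y0:
                continue
            out_boxes.append(BoundingBox(x0, y0, x1, y1, label=name,
                                         score=float(scores[ai])))
            out_anchors.append(ai)
            out_classes.append(ci)
    return DetectionResult(image_id, out_boxes, out_anchors, out_classes)


# ---------------------------------------------------------------------------
# input preparation & checkpointing
# ---------------------------------------------------------------------------

def prepare_input(image: RasterImage, config: NetworkConfig) -> np.ndarray:
    """Normalized (C, H, W) float32 input; grayscale replicated to channels."""
    from skimage.transform import resize as _sk_resize
    px = image.normalized().gray()
    if px.shape != (config.input_size, config.input_size):
        px = _sk_resize(px, (config.input_size, config.input_size),
                        order=1, anti_aliasing=True, preserve_range=True)
    px = (px.astype(np.float32) - 0.5) / 0.25
    return np.repeat(px[None], config.in_channels, axis=0)


def save_checkpoint(path: str | Path, model: SSDDetector, extra: dict | None = None):
    meta = {"config": asdict(model.config)}
    if extra:
        meta["extra"] = extra
    state = model.state_dict()
    np.savez(path, __meta__=np.array(json.dumps(meta)), **state)


def load_checkpoint(path: str | Path) -> SSDDetector:
    with np.load(path, allow_pickle=False) as data:
        meta = json.loads(str(data["__meta__"]))
        state = {k: data[k] for k in data.files if k != "__meta__"}
    cfg_dict = meta["config"]
    for key in ("anchor_sizes", "variances"):
        cfg_dict[key] = tuple(cfg_dict[key])
    model = build_detector(NetworkConfig(**cfg_dict), seed=0)
    model.load_state_dict(state)
    return model
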