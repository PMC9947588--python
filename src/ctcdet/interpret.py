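"""Model interpretation: Grad-CAM heatmaps and t-SNE feature embeddings.

Grad-CAM explains one detection by weighting each feature-map channel with
the spatial mean of the gradient of the detection score with respect to that
channel (``w_k = (1/Z) * sum_ij dY/dA_kij``), summing the weighted channels
(``L = sum_k w_k A_k``), rectifying (negative evidence zeroed; optional, on
by default) and min-max normalizing.  Multi-layer maps are fused as a
normalized weighted sum after bilinear upsampling to the input resolution,
with higher weights on the lower (detail-rich) levels.

The t-SNE embedding is perplexity-calibrated Gaussian affinities in feature
space against Student-t affinities in 2-D, minimizing their KL divergence;
it is backed by scikit-learn's implementation.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
from skimage.transform import resize as _sk_resize

from . import autodiff as ad
from .autodiff import Tensor
from .detector import (DetectionResult, SSDDetector, decode_and_filter,
                       generate_anchors, prepare_input)
from .imaging_io import RasterImage, write_image

__all__ = ["GradCamHeatmap", "EmbeddingResult", "grad_cam", "fuse_heatmaps",
           "explain_detection", "tsne_embed", "backbone_crop_features",
           "DEFAULT_LAYER_WEIGHTS"]

#: low-level maps carry more localization detail, so they weigh more
DEFAULT_LAYER_WEIGHTS = (4.0, 3.0, 2.0, 1.0)


@dataclass
class GradCamHeatmap:
    layer_maps: list[np.ndarray]          # per-layer maps, feature-grid resolution
    channel_weights: list[np.ndarray]     # w_k per layer
    fused: np.ndarray                     # input-resolution map in [0, 1]
    target_class: int
    anchor_index: int | None = None
    layer_weights: tuple = DEFAULT_LAYER_WEIGHTS


@dataclass
class EmbeddingResult:
    coords: np.ndarray        # (n, 2)
    kl_divergence: float
    perplexity: float
    layer: str = ""


def _normalize_map(m: np.ndarray) -> np.ndarray:
    lo, hi = float(m.min()), float(m.max())
    if hi > lo:
        return (m - lo) / (hi - lo)
    return np.zeros_like(m)


def grad_cam(features: list[Tensor], score: Tensor, input_size: int,
             layer_weights: tuple = DEFAULT_LAYER_WEIGHTS,
             rectify: bool = True, target_class: int = 1,
             anchor_index: int | None = None) -> GradCamHeatmap:
    """Class-activation maps from gradients of ``score`` w.r.t. ``features``.

    ``features`` are (1, C, H, W) tensors that participated in the forward
    pass producing the scalar ``score``; the backward pass is run here.
    """
    if not score.requires_grad:
        raise ValueError("score is not connected to a differentiable graph")
    n_layers = len(layer_weights)
    for f in features[:n_layers]:
        f.grad = None
    score.backward()
    layer_maps, channel_weights = [], []
    for f in features[:n_layers]:
        if f.grad is None:
            g = np.zeros_like(f.data)
        else:
            g = f.grad
        w = g.mean(axis=(2, 3))[0]                       # (C,): spatial-mean gradients
        cam = np.tensordot(w, f.data[0], axes=(0, 0))    # (H, W)
        if rectify:
            cam = np.maximum(cam, 0.0)
        layer_maps.append(_normalize_map(cam))
        channel_weights.append(w)
    fused = fuse_heatmaps(layer_maps, layer_weights, input_size)
    return GradCamHeatmap(layer_maps, channel_weights, fused, target_class,
                          anchor_index, tuple(layer_weights))


def fuse_heatmaps(maps: list[np.ndarray], weights, out_size: int) -> np.ndarray:
    """Weighted sum of upsampled maps, renormalized to [0, 1]."""
    weights = np.asarray(weights, dtype=np.float64)
    if len(weights) != len(maps):
        raise ValueError("one weight per map required")
    if np.any(weights < 0) or weights.sum() <= 0:
        raise ValueError("weights must be nonnegative with a nonzero sum")
    weights = weights / weights.sum()
    acc = np.zeros((out_size, out_size))
    for m, w in zip(maps, weights):
        if w == 0:
            continue
        up = _sk_resize(m.astype(np.float64), (out_size, out_size), order=1,
                        anti_aliasing=False, preserve_range=True)
        acc += w * up
    return _normalize_map(acc)


def explain_detection(model: SSDDetector, image: RasterImage, detection_index: int,
                      layer_weights: tuple = DEFAULT_LAYER_WEIGHTS,
                      score_type: str = "logit", rectify: bool = True,
                      overlay_path: str | Path | None = None,
                      score_threshold: float | None = None,
                      ) -> tuple[GradCamHeatmap, DetectionResult, np.ndarray]:
    """Grad-CAM for one NMS-surviving detection of an image.

    ``score_type`` selects the scalar Y backpropagated: the pre-softmax class
    logit of the detection's anchor (default) or its normalized probability.
    """
    config = model.config
    anchors = generate_anchors(config)
    x = prepare_input(image, config)[None]
    conf, loc, feats = model.forward(x)
    result = decode_and_filter(conf.data[0], loc.data[0], anchors, config,
                               image_id=image_id_of(image),
                               score_threshold=score_threshold)
    if not (0 <= detection_index < len(result.boxes)):
        raise IndexError(f"detection index {detection_index} out of range "
                         f"({len(result.boxes)} detections)")
    ai = result.anchor_indices[detection_index]
    ci = result.class_indices[detection_index]
    conf2d = ad.reshape(conf, conf.shape[1:])
    if score_type == "logit":
        y = ad.tsum(ad.take2d(conf2d, np.array([ai]), np.array([ci])))
    elif score_type == "prob":
        lsm = ad.log_softmax(conf2d, axis=1)
        y = ad.tsum(ad.exp(ad.take2d(lsm, np.array([ai]), np.array([ci]))))
    else:
        raise ValueError("score_type must be 'logit' or 'prob'")
    heatmap = grad_cam(feats, y, config.input_size, layer_weights,
                       rectify=rectify, target_class=ci, anchor_index=ai)
    model.zero_grad()
    overlay = render_overlay(image, heatmap.fused)
    if overlay_path is not None:
        write_image(RasterImage(overlay, 8), overlay_path)
    return heatmap, result, overlay


def image_id_of(image: RasterImage) -> str:
    return f"image_{image.height}x{image.width}"


def render_overlay(image: RasterImage, heat: np.ndarray, alpha: float = 0.45) -> np.ndarray:
    """Blend a color-mapped heatmap over the (resized) grayscale image."""
    from matplotlib import colormaps
    gray = image.normalized().gray()
    if gray.shape != heat.shape:
        gray = _sk_resize(gray, heat.shape, order=1, anti_aliasing=True,
                          preserve_range=True)
    rgb = np.repeat(gray[..., None], 3, axis=2)
    cmap = colormaps["jet"](heat)[..., :3]
    out = (1.0 - alpha) * rgb + alpha * cmap
    return (np.clip(out, 0, 1) * 255).astype(np.uint8)


# ---------------------------------------------------------------------------
# feature extraction + t-SNE
# ---------------------------------------------------------------------------

def backbone_crop_features(model: SSDDetector, crops: list[RasterImage],
                           size: int = 48, depth: int = 3,
                           batch_size: int = 32) -> np.ndarray:
    """Spatial-mean-pooled backbone activations for single-cell crops.

    Crops are resized to ``size`` px, passed through the first ``depth``
    backbone blocks (pooling between blocks), and mean-pooled over space.
    A pure read: model parameters and buffers are untouched.
    """
    xs = []
    for crop in crops:
        px = crop.normalized().gray()
        px = _sk_resize(px, (size, size), order=1, anti_aliasing=True,
                        preserve_range=True)
        px = (px.astype(np.float32) - 0.5) / 0.25
        xs.append(np.repeat(px[None], model.config.in_channels, axis=0))
    out = []
    with ad.no_grad():
        for start in range(0, len(xs), batch_size):
            f = Tensor(np.stack(xs[start:start + batch_size]))
            for bi in range(depth):
                for layer in model.blocks[bi]:
                    f = layer(f)
                if bi < depth - 1:
                    f = ad.maxpool2d(f, 2, ceil_mode=True)
            out.append(f.data.mean(axis=(2, 3)))
    return np.concatenate(out, axis=0)


def tsne_embed(features: np.ndarray, perplexity: float = 30.0, seed: int = 0,
               iterations: int = 1000, layer: str = "") -> EmbeddingResult:
    """2-D t-SNE of per-item feature vectors; deterministic for a fixed seed."""
    features = np.asarray(features, dtype=np.float64)
    if features.ndim != 2:
        raise ValueError("features must be (n_items, n_features)")
    if not np.all(np.isfinite(features)):
        raise ValueError("features must be finite")
    n = features.shape[0]
    if n < 3 * perplexity:
        raise ValueError(f"need at least {int(3 * perplexity)} items for "
                         f"perplexity {perplexity}, got {n}")
    from sklearn.manifold import TSNE
    tsne = TSNE(n_components=2, perplexity=perplexity, random_state=seed,
                max_iter=iterations, init="pca")
    coords = tsne.fit_transform(features)
    return EmbeddingResult(coords, float(tsne.kl_divergence_), perplexity, layer)
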