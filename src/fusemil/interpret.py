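"""Attention rollout, tile classification maps and overlay rendering.

Attention rollout attributes the slide-level prediction to individual
tiles: per layer, the head-averaged attention matrix is mixed with the
identity (coefficient 1/2) to account for residual connections, and the
mixed matrices are multiplied across layers. The CLS row of the product,
restricted to tile columns, is the per-tile attention mass. Multiplying it
element-wise with per-tile classification scores highlights tiles that are
both influential and predictive — regions with high classification scores
but negligible attention contribute little to the slide-level call.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from matplotlib import colormaps

from .aggregator import Aggregator, tile_scores as _tile_scores


@dataclass
class HeatmapBundle:
    attention: np.ndarray          # per-tile rollout mass (CLS row)
    classification: np.ndarray     # per-tile probabilities
    combined: np.ndarray           # element-wise product
    coords: np.ndarray
    overlays: dict = field(default_factory=dict)


def attention_rollout(attn) -> np.ndarray:
    """Per-tile attention via rollout.

    ``attn`` is (n_layers, n_heads, T, T) with row-stochastic rows (T =
    n_tiles + 1, token 0 is CLS). Per layer: average heads -> A, mix
    residual -> 0.5 * A + 0.5 * I; multiply the mixed matrices last layer
    first; return the CLS row over tile columns (CLS self-mass excluded,
    not re-normalized).
    """
    attn = np.asarray(attn, dtype=np.float64)
    if attn.ndim != 4 or attn.shape[-1] != attn.shape[-2]:
        raise ValueError("attention must be (n_layers, n_heads, T, T)")
    row_err = np.abs(attn.sum(axis=-1) - 1.0).max()
    if row_err > 1e-3:
        raise ValueError(f"attention rows not stochastic (max error {row_err:.2e})")
    T = attn.shape[-1]
    rollout = np.eye(T)
    for layer in range(attn.shape[0]):
        mixed = 0.5 * attn[layer].mean(axis=0) + 0.5 * np.eye(T)
        rollout = mixed @ rollout
    return rollout[0, 1:]


def classification_map(model: Aggregator, bag) -> np.ndarray:
    """Per-tile fusion probabilities (singleton-bag pathway)."""
    return _tile_scores(model, bag)


def combined_map(attention: np.ndarray, classification: np.ndarray) -> np.ndarray:
    """Element-wise attention x classification."""
    attention = np.asarray(attention, dtype=float)
    classification = np.asarray(classification, dtype=float)
    if attention.shape != classification.shape:
        raise ValueError("attention and classification lengths differ")
    return attention * classification


def build_heatmaps(model: Aggregator, bag, thumbnail=None, scale: float = 1.0,
                   tile_size: int = 224) -> HeatmapBundle:
    """Full interpretation bundle for one bag; renders overlays when a
    thumbnail is supplied."""
    from .aggregator import forward_bag

    out = forward_bag(model, bag)
    attention = attention_rollout(out.attention)
    classification = classification_map(model, bag)
    bundle = HeatmapBundle(attention=attention, classification=classification,
                           combined=combined_map(attention, classification),
                           coords=np.asarray(bag.coords))
    if thumbnail is not None:
        bundle.overlays = {
            "attention": render_overlay(attention, bag.coords, thumbnail,
                                        colormap="viridis", scale=scale,
                                        tile_size=tile_size),
            "classification": render_overlay(classification, bag.coords, thumbnail,
                                             colormap="Reds", scale=scale,
                                             tile_size=tile_size),
            "combined": render_overlay(bundle.combined, bag.coords, thumbnail,
                                       colormap="inferno", scale=scale,
                                       tile_size=tile_size),
        }
    return bundle


def render_overlay(scores, coords, thumbnail, colormap: str = "viridis",
                   scale: float = 1.0, tile_size: int = 224,
                   alpha: float = 0.6, legend_width: int = 12) -> np.ndarray:
    """Color each tile footprint on (a copy of) the thumbnail by its score.

    Scores are min-max scaled for display only; a vertical legend strip of
    the colormap is appended on the right. The input image is not
    modified. Coordinates are at working resolution and mapped into the
    thumbnail frame by ``scale`` (thumbnail -> working factor).
    """
    scores = np.asarray(scores, dtype=float)
    coords = np.asarray(coords).reshape(-1, 2)
    if len(scores) != len(coords):
        raise ValueError("scores and coords lengths differ")
    img = np.asarray(thumbnail)
    if img.ndim == 2:
        img = np.stack([img] * 3, axis=-1)
    out = img.astype(np.float64).copy()
    if out.max() > 1.5:
        out /= 255.0

    span = scores.max() - scores.min()
    display = (scores - scores.min()) / span if span > 0 else np.full_like(scores, 0.5)
    cmap = colormaps[colormap]
    ts = max(1, int(round(tile_size / scale)))
    H, W = out.shape[:2]
    for val, (x, y) in zip(display, coords):
        cx, cy = int(round(x / scale)), int(round(y / scale))
        if cx < 0 or cy < 0 or cx >= W or cy >= H:
            raise ValueError(f"tile at ({x}, {y}) falls outside the thumbnail")
        color = np.array(cmap(float(val))[:3])
        patch = out[cy:cy + ts, cx:cx + ts]
        patch[:] = (1 - alpha) * patch + alpha * color
    legend = cmap(np.linspace(1.0, 0.0, H))[:, None, :3]
    legend = np.repeat(legend, legend_width, axis=1)
    return np.concatenate([out, legend], axis=1)
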