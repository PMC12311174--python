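"""Tissue masking and tiling.

A whole slide is reduced to a low-resolution thumbnail, and a binary
tissue mask is refined stage by stage: blurry regions are dropped via a
Gaussian-smoothed Laplacian criterion, flat background via a local
mean-deviation criterion, then morphology removes small objects and fills
small holes, and finally enclosed fat-like (near-white) regions and dark
rectangular label artifacts are excised. Non-overlapping tiles are then
emitted wherever the mask covers enough of a grid-aligned footprint.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from skimage import color, measure, morphology, transform

DEFAULT_MASK_CONFIG = {
    "blur_sigma": 2.0,
    "blur_threshold": 0.05,     # fraction of intensity range, on |Laplacian|
    "flat_window": 15,
    "flat_tol": 0.04,           # fraction of intensity range
    "min_object": 64,           # px at thumbnail scale
    "max_hole": 64,
    "density_tol": 0.85,        # near-white cutoff for fat-like regions
    "dark_tol": 0.30,           # near-black cutoff for label artifacts
    "rect_min": 0.60,           # rectangularity (area / bbox area) cutoff
    "fat_min_size": 8,          # px; smaller bright specks are texture
}


@dataclass
class TissueMask:
    """Binary thumbnail-scale mask plus per-stage provenance."""

    mask: np.ndarray
    scale: float                      # thumbnail -> full resolution factor
    stage_log: list = field(default_factory=list)

    @property
    def shape(self):
        return self.mask.shape


@dataclass
class TileSet:
    """Grid-aligned, non-overlapping tile coordinates at working resolution."""

    slide_id: str
    tile_size: int
    magnification: float
    coords: np.ndarray               # (n, 2) of (x, y) top-left

    def __post_init__(self):
        self.coords = np.asarray(self.coords, dtype=np.int64).reshape(-1, 2)

    def __len__(self):
        return self.coords.shape[0]


def _to_gray(image: np.ndarray) -> np.ndarray:
    """Grayscale in [0, 1] from uint8/float RGB or a 2-D array."""
    img = np.asarray(image)
    if img.ndim == 3:
        g = color.rgb2gray(img)
    else:
        g = img.astype(np.float64)
        if g.max() > 1.5:
            g = g / 255.0
    return g


def extract_thumbnail(slide_image: np.ndarray, target_downsample: float) -> np.ndarray:
    """Downsample a slide image by ``target_downsample``, preserving aspect."""
    img = np.asarray(slide_image)
    if img.size == 0:
        raise ValueError("empty slide image")
    if target_downsample < 1:
        raise ValueError("target_downsample must be >= 1")
    if target_downsample == 1:
        return img.copy()
    h = int(np.ceil(img.shape[0] / target_downsample))
    w = int(np.ceil(img.shape[1] / target_downsample))
    out_shape = (h, w) + img.shape[2:]
    thumb = transform.resize(img, out_shape, anti_aliasing=True, preserve_range=True)
    if np.issubdtype(img.dtype, np.integer):
        thumb = np.clip(np.round(thumb), 0, 255).astype(img.dtype)
    return thumb


def blur_mask(thumbnail: np.ndarray, sigma: float = 2.0,
              threshold: float = 0.05) -> np.ndarray:
    """Keep pixels whose Gaussian-smoothed |Laplacian| is >= threshold.

    Blurry patches and flat background have weak local edges and are
    dropped; sharp tissue texture survives.
    """
    if sigma <= 0:
        raise ValueError("sigma must be > 0")
    gray = _to_gray(thumbnail)
    lap = np.abs(ndimage.laplace(gray))
    smooth = ndimage.gaussian_filter(lap, sigma)
    return smooth >= threshold


def flat_mask(thumbnail: np.ndarray, window: int = 15,
              flat_tol: float = 0.04) -> np.ndarray:
    """Drop pixels whose local mean absolute deviation from the window mean
    is below ``flat_tol`` (uniform-intensity background)."""
    if window < 3 or window % 2 == 0:
        raise ValueError("window must be odd and >= 3")
    gray = _to_gray(thumbnail)
    local_mean = ndimage.uniform_filter(gray, window)
    dev = ndimage.uniform_filter(np.abs(gray - local_mean), window)
    return dev >= flat_tol


def refine_mask(mask: np.ndarray, min_object: int = 64,
                max_hole: int = 64) -> np.ndarray:
    """Remove foreground components smaller than ``min_object`` pixels and
    fill enclosed holes smaller than ``max_hole`` pixels. Components of size
    exactly ``min_object`` are kept."""
    out = mask.astype(bool)
    if min_object > 1:
        out = morphology.remove_small_objects(out, max_size=min_object - 1)
    if max_hole > 1:
        out = morphology.remove_small_holes(out, max_size=max_hole - 1)
    return out


def remove_fat_and_dark(mask: np.ndarray, thumbnail: np.ndarray,
                        density_tol: float = 0.85, dark_tol: float = 0.30,
                        rect_min: float = 0.60, fat_min_size: int = 8) -> np.ndarray:
    """Excise fat-like enclosed near-white regions and dark label artifacts.

    Fat: connected near-white (> density_tol) regions inside the mask that
    do not touch the image border. Dark labels: mask components whose
    median intensity is below ``dark_tol`` and whose rectangularity (area
    over bounding-box area) exceeds ``rect_min``. The median (not mean) is
    used for darkness so that the thin bright halo the edge filters keep
    around a label cannot disguise it.
    """
    if mask.shape != _to_gray(thumbnail).shape:
        raise ValueError("mask and thumbnail shapes differ")
    gray = _to_gray(thumbnail)
    out = mask.astype(bool).copy()

    # enclosed near-white (fat-like) regions; isolated bright texture
    # speckles below fat_min_size are not fat
    candidates = out & (gray > density_tol)
    lab, n = ndimage.label(candidates)
    if n:
        border = np.zeros_like(out)
        border[0, :] = border[-1, :] = border[:, 0] = border[:, -1] = True
        border_labels = set(np.unique(lab[border])) - {0}
        sizes = np.bincount(lab.ravel())
        for region in range(1, n + 1):
            if region not in border_labels and sizes[region] >= fat_min_size:
                out[lab == region] = False

    # dark, rectangular artifacts
    lab, n = ndimage.label(out)
    for props in measure.regionprops(lab):
        if np.median(gray[lab == props.label]) < dark_tol:
            bbox_area = (props.bbox[2] - props.bbox[0]) * (props.bbox[3] - props.bbox[1])
            if props.area / bbox_area > rect_min:
                out[lab == props.label] = False
    return out


def build_tissue_mask(thumbnail: np.ndarray, config: dict | None = None,
                      scale: float = 1.0) -> TissueMask:
    """Run the full refinement chain, recording a per-stage log of signed
    pixel deltas (negative = removed)."""
    cfg = dict(DEFAULT_MASK_CONFIG)
    if config:
        cfg.update(config)
    log = []

    keep_blur = blur_mask(thumbnail, cfg["blur_sigma"], cfg["blur_threshold"])
    keep_flat = flat_mask(thumbnail, cfg["flat_window"], cfg["flat_tol"])
    mask = keep_blur & keep_flat
    log.append(("blur", int(keep_blur.sum()) - keep_blur.size))
    log.append(("flat", int(mask.sum()) - int(keep_blur.sum())))

    before = int(mask.sum())
    no_small = refine_mask(mask, cfg["min_object"], max_hole=0)
    log.append(("remove_small_objects", int(no_small.sum()) - before))
    filled = refine_mask(no_small, min_object=0, max_hole=cfg["max_hole"])
    log.append(("fill_holes", int(filled.sum()) - int(no_small.sum())))

    final = remove_fat_and_dark(filled, thumbnail, cfg["density_tol"],
                                cfg["dark_tol"], cfg["rect_min"],
                                cfg["fat_min_size"])
    log.append(("fat_dark", int(final.sum()) - int(filled.sum())))
    return TissueMask(mask=final, scale=scale, stage_log=log)


def _integral(mask: np.ndarray) -> np.ndarray:
    s = np.zeros((mask.shape[0] + 1, mask.shape[1] + 1))
    s[1:, 1:] = np.cumsum(np.cumsum(mask.astype(np.float64), 0), 1)
    return s


def _sample_integral(s: np.ndarray, y: float, x: float) -> float:
    """Bilinear sample of the integral image; exact for piecewise-constant
    masks at fractional footprints."""
    y = min(max(y, 0.0), s.shape[0] - 1.0)
    x = min(max(x, 0.0), s.shape[1] - 1.0)
    y0, x0 = int(np.floor(y)), int(np.floor(x))
    y1, x1 = min(y0 + 1, s.shape[0] - 1), min(x0 + 1, s.shape[1] - 1)
    fy, fx = y - y0, x - x0
    top = s[y0, x0] * (1 - fx) + s[y0, x1] * fx
    bot = s[y1, x0] * (1 - fx) + s[y1, x1] * fx
    return top * (1 - fy) + bot * fy


def tile_slide(tissue: TissueMask, image_dims: tuple, slide_id: str = "",
               tile_size: int = 224, coverage_min: float = 0.5,
               magnification: float = 10.0) -> TileSet:
    """Emit grid-aligned non-overlapping tiles whose footprint is covered by
    the mask for at least ``coverage_min`` of its area.

    ``image_dims`` is (width, height) at working resolution; mask footprints
    are mapped through ``tissue.scale``. A tile_size larger than the image
    yields an empty tile set.
    """
    if not (0.0 < coverage_min <= 1.0):
        raise ValueError("coverage_min must lie in (0, 1]")
    W, H = image_dims
    s = _integral(tissue.mask)
    inv = 1.0 / tissue.scale
    coords = []
    for y in range(0, H - tile_size + 1, tile_size):
        for x in range(0, W - tile_size + 1, tile_size):
            y0, y1 = y * inv, (y + tile_size) * inv
            x0, x1 = x * inv, (x + tile_size) * inv
            covered = (_sample_integral(s, y1, x1) - _sample_integral(s, y0, x1)
                       - _sample_integral(s, y1, x0) + _sample_integral(s, y0, x0))
            area = (y1 - y0) * (x1 - x0)
            if covered / area >= coverage_min:
                coords.append((x, y))
    return TileSet(slide_id=slide_id, tile_size=tile_size,
                   magnification=magnification,
                   coords=np.array(coords, dtype=np.int64).reshape(-1, 2))
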