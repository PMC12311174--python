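"""Synthetic slides, feature-bag datasets and specimen thumbnails.

The generators emulate the statistical structure the pipeline assumes on
real whole-slide data: slide images carry textured tissue on a near-white
background plus the three artifact classes the tissue masking chain must
reject (blurred patches, dark printed-label rectangles, enclosed fat-like
holes); feature-bag datasets carry three rare, mutually exclusive fusion
sub-labels (ROS1 / ALK / NTRK) whose positive bags hide a shared "fusion"
signal plus a sub-label-specific component in a small fraction of tiles.
Fixing the seed fixes every output bit-exactly.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage

SUB_LABELS = ("ROS1", "ALK", "NTRK")


# ---------------------------------------------------------------------------
# slide images
# ---------------------------------------------------------------------------

@dataclass
class SynthSlideSpec:
    """Recipe for one synthetic slide image.

    Rects are (x, y, w, h) in pixel units, 0-based, x right / y down.
    ``tissue_rects`` pins tissue blobs to known rectangles (useful for
    ground-truth area checks); when empty, ``tissue_blobs`` elliptical blobs
    are placed randomly by the seed.
    """

    width: int = 384
    height: int = 384
    tissue_blobs: int = 2
    tissue_rects: list = field(default_factory=list)
    blur_patches: list = field(default_factory=list)
    dark_labels: list = field(default_factory=list)
    fat_holes: list = field(default_factory=list)
    seed: int = 0

    def validate(self):
        for rect in list(self.tissue_rects) + list(self.blur_patches) + \
                list(self.dark_labels) + list(self.fat_holes):
            x, y, w, h = rect
            if w <= 0 or h <= 0 or x < 0 or y < 0 or \
                    x + w > self.width or y + h > self.height:
                raise ValueError(f"planted region {rect} outside image bounds")


def _rect_mask(shape, rect):
    m = np.zeros(shape, dtype=bool)
    x, y, w, h = rect
    m[y:y + h, x:x + w] = True
    return m


def gen_synthetic_slide(spec: SynthSlideSpec):
    """Render the slide and return ``(image, masks)``.

    ``image`` is (H, W, 3) uint8. ``masks`` maps class name to a boolean
    ground-truth mask: ``tissue`` is the artifact-free tissue (planted
    tissue minus blur patches and fat holes), plus one mask per planted
    artifact class (``blur``, ``dark``, ``fat``) and the raw planted
    tissue under ``tissue_raw``.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    H, W = spec.height, spec.width
    shape = (H, W)

    # near-white background with faint scanner noise
    img = np.empty((H, W, 3), dtype=np.float64)
    base = 240.0 + rng.normal(0.0, 2.0, size=shape)
    img[...] = base[..., None]

    # tissue: eosin-like mid tone with strong texture
    tissue = np.zeros(shape, dtype=bool)
    if spec.tissue_rects:
        for rect in spec.tissue_rects:
            tissue |= _rect_mask(shape, rect)
    elif spec.tissue_blobs > 0:
        yy, xx = np.mgrid[0:H, 0:W]
        for _ in range(spec.tissue_blobs):
            cx = rng.uniform(0.25 * W, 0.75 * W)
            cy = rng.uniform(0.25 * H, 0.75 * H)
            rx = rng.uniform(0.14 * W, 0.22 * W)
            ry = rng.uniform(0.14 * H, 0.22 * H)
            theta = rng.uniform(0, np.pi)
            xr = (xx - cx) * np.cos(theta) + (yy - cy) * np.sin(theta)
            yr = -(xx - cx) * np.sin(theta) + (yy - cy) * np.cos(theta)
            tissue |= (xr / rx) ** 2 + (yr / ry) ** 2 <= 1.0

    texture = rng.normal(0.0, 26.0, size=shape)
    tissue_rgb = np.stack([
        172.0 + texture, 132.0 + 0.8 * texture, 168.0 + 0.9 * texture
    ], axis=-1)
    img[tissue] = tissue_rgb[tissue]

    # fat-like enclosed holes: near-white, low texture, inside tissue
    fat = np.zeros(shape, dtype=bool)
    for rect in spec.fat_holes:
        m = _rect_mask(shape, rect)
        if not (m <= tissue).all():
            raise ValueError(f"fat hole {rect} not enclosed by tissue")
        fat |= m
    img[fat] = (236.0 + rng.normal(0.0, 2.0, size=(int(fat.sum()), 3)))

    # blurred patches: feathered so the blur/sharp boundary is smooth
    blur = np.zeros(shape, dtype=bool)
    if spec.blur_patches:
        blurred = np.stack([
            ndimage.gaussian_filter(img[..., c], 3.0) for c in range(3)
        ], axis=-1)
        weight = np.zeros(shape, dtype=np.float64)
        for rect in spec.blur_patches:
            weight = np.maximum(weight, _rect_mask(shape, rect).astype(float))
        weight = ndimage.gaussian_filter(weight, 3.0)
        img = weight[..., None] * blurred + (1.0 - weight[..., None]) * img
        for rect in spec.blur_patches:
            blur |= _rect_mask(shape, rect)
        blur &= tissue

    # dark printed-label artifacts: near-black, textured, off-tissue
    dark = np.zeros(shape, dtype=bool)
    for rect in spec.dark_labels:
        m = _rect_mask(shape, rect)
        if (m & (tissue | fat)).any():
            raise ValueError(f"dark label {rect} overlaps a conflicting class")
        dark |= m
    img[dark] = np.clip(
        28.0 + rng.normal(0.0, 16.0, size=(int(dark.sum()), 3)), 0, 255)

    masks = {
        "tissue_raw": tissue,
        "tissue": tissue & ~blur & ~fat,
        "blur": blur,
        "dark": dark,
        "fat": fat,
    }
    return np.clip(img, 0, 255).astype(np.uint8), masks


def random_slide_spec(seed: int, width: int = 384, height: int = 384) -> SynthSlideSpec:
    """Draw a consistent random slide spec: one large central tissue blob
    with a blur patch and a fat hole inside it, and a dark label in a
    tissue-free margin. Region sizes scale with the image dimensions."""
    rng = np.random.default_rng(seed)

    def u(lo, hi, dim):
        return int(rng.integers(int(lo * dim), int(hi * dim)))

    bx, by = u(0.23, 0.31, width), u(0.23, 0.31, height)
    bw, bh = u(0.44, 0.52, width), u(0.44, 0.52, height)
    tissue_rect = (bx, by, bw, bh)
    blur_rect = (bx + u(0.02, 0.04, width), by + u(0.02, 0.04, height),
                 u(0.15, 0.19, width), u(0.15, 0.19, height))
    fat_side = max(12, int(0.068 * min(width, height)))
    fat_rect = (bx + bw - fat_side - u(0.07, 0.10, width),
                by + bh - fat_side - u(0.07, 0.10, height), fat_side, fat_side)
    dark_rect = (u(0.01, 0.05, width), u(0.01, 0.05, height),
                 u(0.10, 0.15, width), u(0.05, 0.09, height))
    return SynthSlideSpec(
        width=width, height=height, tissue_blobs=0,
        tissue_rects=[tissue_rect], blur_patches=[blur_rect],
        dark_labels=[dark_rect], fat_holes=[fat_rect], seed=seed)


# ---------------------------------------------------------------------------
# feature bags
# ---------------------------------------------------------------------------

@dataclass
class SynthBagSpec:
    """Recipe for a feature-bag dataset with three rare, mutually exclusive
    fusion sub-labels.

    ``shared_effect`` and ``specific_effect`` are standardized shifts (in
    units of ``noise_sd``) applied along fixed orthonormal directions to a
    ``signal_tile_frac`` fraction of tiles in positive bags.
    ``heterogeneity`` adds a random per-slide direction of the same
    standardized magnitude to each positive slide's signal, emulating
    patient-to-patient morphological variability: a model trained on very
    few positives latches onto their idiosyncratic components, while the
    shared component only emerges from many positives. The default
    prevalences mirror the relative rarity of ROS1 / ALK / NTRK fusions in
    non-small cell lung cancer (roughly 1% / 2% / sub-1%).
    """

    n_slides: int = 1000
    bag_size_range: tuple = (15, 40)
    d: int = 16
    prevalence: tuple = (0.01, 0.02, 0.005)
    shared_effect: float = 2.0
    specific_effect: float = 1.0
    heterogeneity: float = 2.0
    signal_tile_frac: float = 0.25
    noise_sd: float = 1.0
    seed: int = 0

    def validate(self):
        if self.d < 4:
            raise ValueError(
                "d must be >= 4 to hold the shared + 3 sub-label orthonormal directions")
        if not (0.0 < self.signal_tile_frac <= 1.0):
            raise ValueError("signal_tile_frac must lie in (0, 1]")
        if len(self.prevalence) != 3:
            raise ValueError("prevalence must have one entry per sub-label")
        for p in self.prevalence:
            if not (0.0 < p < 1.0):
                raise ValueError("prevalences must lie in (0, 1)")
        if sum(self.prevalence) >= 1.0:
            raise ValueError("prevalences must sum to < 1")
        for p in self.prevalence:
            if p * self.n_slides < 1:
                raise ValueError("prevalence * n_slides must be >= 1 per sub-label")


@dataclass
class FeatureBag:
    """One slide's tile features: an (n_tiles, d) matrix plus grid coords."""

    slide_id: str
    features: np.ndarray
    coords: np.ndarray

    def __post_init__(self):
        self.features = np.asarray(self.features, dtype=np.float64)
        self.coords = np.asarray(self.coords, dtype=np.int64).reshape(-1, 2)
        if self.features.shape[0] != self.coords.shape[0]:
            raise ValueError("features and coords row counts differ")

    @property
    def n_tiles(self):
        return self.features.shape[0]

    @property
    def d(self):
        return self.features.shape[1]


def signal_directions(d: int, seed: int) -> dict:
    """Fixed orthonormal directions u_shared, u_ROS1, u_ALK, u_NTRK per seed."""
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 0x5157]))
    q, _ = np.linalg.qr(rng.normal(size=(d, 4)))
    names = ("shared",) + SUB_LABELS
    return {name: q[:, i].copy() for i, name in enumerate(names)}


def gen_bag_dataset(spec: SynthBagSpec):
    """Generate bags and a label manifest.

    Returns ``(bags, manifest)``: a list of :class:`FeatureBag` and a
    DataFrame with columns slide_id, ROS1, ALK, NTRK, specimen_type. Bags
    record which tiles carry planted signal in ``bag.signal_tiles``
    (attached attribute, boolean per tile).
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    dirs = signal_directions(spec.d, spec.seed)

    p = np.asarray(spec.prevalence, dtype=float)
    # category per slide: 0..2 sub-label positive, 3 negative
    cats = rng.choice(4, size=spec.n_slides, p=np.append(p, 1.0 - p.sum()))

    bags, rows = [], []
    lo, hi = spec.bag_size_range
    for i in range(spec.n_slides):
        n = int(rng.integers(lo, hi + 1))
        feats = rng.normal(0.0, spec.noise_sd, size=(n, spec.d))
        signal = np.zeros(n, dtype=bool)
        cat = int(cats[i])
        if cat < 3:
            k = max(1, int(np.ceil(spec.signal_tile_frac * n)))
            idx = rng.choice(n, size=k, replace=False)
            own = rng.normal(size=spec.d)
            own /= np.linalg.norm(own)
            shift = (spec.shared_effect * dirs["shared"] +
                     spec.specific_effect * dirs[SUB_LABELS[cat]] +
                     spec.heterogeneity * own) * spec.noise_sd
            feats[idx] += shift
            signal[idx] = True
        side = int(np.ceil(np.sqrt(n)))
        coords = np.stack([(np.arange(n) % side) * 224,
                           (np.arange(n) // side) * 224], axis=1)
        bag = FeatureBag(slide_id=f"S{i:05d}", features=feats, coords=coords)
        bag.signal_tiles = signal
        bags.append(bag)
        rows.append({
            "slide_id": bag.slide_id,
            "ROS1": cat == 0, "ALK": cat == 1, "NTRK": cat == 2,
            "specimen_type": "biopsy" if rng.random() < 0.5 else "resection",
        })
    manifest = pd.DataFrame(rows)
    return bags, manifest


# ---------------------------------------------------------------------------
# specimen thumbnails
# ---------------------------------------------------------------------------

def gen_specimen_thumbnails(n: int, seed: int, size: int = 96):
    """Balanced biopsy/resection thumbnails.

    Biopsies show several small scattered tissue fragments; resections show
    one large contiguous region. Returns ``(images, labels)`` with images
    (n, size, size, 3) uint8 and labels an array of "biopsy"/"resection".
    """
    if n < 2:
        raise ValueError("n must be >= 2")
    rng = np.random.default_rng(seed)
    n_biopsy = n // 2
    labels = np.array(["biopsy"] * n_biopsy + ["resection"] * (n - n_biopsy))
    perm = rng.permutation(n)
    labels = labels[perm]

    yy, xx = np.mgrid[0:size, 0:size].astype(float)
    images = np.empty((n, size, size, 3), dtype=np.uint8)
    for i, lab in enumerate(labels):
        img = 240.0 + rng.normal(0.0, 2.0, size=(size, size))
        mask = np.zeros((size, size), dtype=bool)
        if lab == "biopsy":
            n_frag = int(rng.integers(5, 9))
            for _ in range(n_frag):
                cx, cy = rng.uniform(0.1 * size, 0.9 * size, size=2)
                r = rng.uniform(0.03 * size, 0.06 * size)
                mask |= (xx - cx) ** 2 + (yy - cy) ** 2 <= r ** 2
        else:
            cx, cy = rng.uniform(0.4 * size, 0.6 * size, size=2)
            rx = rng.uniform(0.28 * size, 0.38 * size)
            ry = rng.uniform(0.28 * size, 0.38 * size)
            mask |= ((xx - cx) / rx) ** 2 + ((yy - cy) / ry) ** 2 <= 1.0
        tex = 165.0 + rng.normal(0.0, 18.0, size=(size, size))
        img = np.where(mask, tex, img)
        rgb = np.stack([img, img * 0.82, img * 0.95], axis=-1)
        images[i] = np.clip(rgb, 0, 255).astype(np.uint8)
    return images, labels


def fragment_count(image: np.ndarray, threshold: float = 210.0) -> int:
    """Connected-component count of the tissue foreground of a thumbnail
    (the oracle statistic that separates biopsy from resection)."""
    gray = image[..., 0].astype(float)
    fg = gray < threshold
    fg = ndimage.binary_opening(fg, structure=np.ones((2, 2)))
    _, count = ndimage.label(fg)
    return int(count)
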