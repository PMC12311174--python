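"""Self-supervised dual-encoder contrastive pretraining of a tile backbone.

Momentum-contrast training with a vision-transformer backbone: a query
encoder updated by gradient descent and a key encoder updated only by an
exponential moving average of the query parameters. Two random
augmentations of the same tile form a positive pair; the other keys in the
batch are negatives; the InfoNCE loss pulls matching views together at
temperature tau. After pretraining, every tile of a slide is mapped through
the query backbone to a d-dimensional feature vector (default 384) and the
vectors are stacked into the slide's feature bag.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from skimage import transform as sk_transform

from . import nn
from .aggregator import init_transformer_layer, transformer_layer
from .nn import Tensor
from .synthetic import FeatureBag


@dataclass
class EncoderConfig:
    img_size: int = 224
    patch_size: int = 16
    d_model: int = 64
    n_layers: int = 2
    n_heads: int = 4
    d_ff: int = 128
    d: int = 384                   # backbone output feature dimension
    proj_hidden: int = 64
    proj_dim: int = 32             # contrastive embedding dimension
    momentum: float = 0.99
    tau: float = 0.2
    lr: float = 1e-3
    batch_size: int = 16
    steps: int = 100
    seed: int = 0

    def validate(self):
        if self.img_size % self.patch_size != 0:
            raise ValueError("patch_size must divide img_size")
        if not (0.0 <= self.momentum <= 1.0):
            raise ValueError("momentum must lie in [0, 1]")
        if self.tau <= 0:
            raise ValueError("tau must be > 0")


@dataclass
class EncoderState:
    """Query/key parameter sets plus the training configuration.

    The key parameters never receive gradients; they are moved only by
    :func:`momentum_update`.
    """

    config: EncoderConfig
    query_params: dict
    key_params: dict
    loss_trace: list = field(default_factory=list)


# ---------------------------------------------------------------------------
# backbone
# ---------------------------------------------------------------------------

def _init_backbone(rng, cfg: EncoderConfig, trainable: bool) -> dict:
    p = {}
    patch_dim = cfg.patch_size * cfg.patch_size * 3
    w, b = nn.init_linear(rng, patch_dim, cfg.d_model)
    p["embed.w"], p["embed.b"] = w, b
    p["cls"] = nn.parameter(rng.normal(0.0, 0.02, size=(1, cfg.d_model)))
    for i in range(cfg.n_layers):
        init_transformer_layer(rng, p, f"layer{i}", cfg.d_model, cfg.d_ff)
    p["ln_f.g"] = nn.parameter(np.ones(cfg.d_model))
    p["ln_f.b"] = nn.parameter(np.zeros(cfg.d_model))
    w, b = nn.init_linear(rng, cfg.d_model, cfg.d)
    p["feat.w"], p["feat.b"] = w, b
    # contrastive projection head (both encoders)
    w, b = nn.init_linear(rng, cfg.d, cfg.proj_hidden)
    p["proj1.w"], p["proj1.b"] = w, b
    w, b = nn.init_linear(rng, cfg.proj_hidden, cfg.proj_dim)
    p["proj2.w"], p["proj2.b"] = w, b
    # prediction head (used by the query encoder only)
    w, b = nn.init_linear(rng, cfg.proj_dim, cfg.proj_hidden)
    p["pred1.w"], p["pred1.b"] = w, b
    w, b = nn.init_linear(rng, cfg.proj_hidden, cfg.proj_dim)
    p["pred2.w"], p["pred2.b"] = w, b
    if not trainable:
        for t in p.values():
            t.requires_grad = False
    return p


def _patchify(image: np.ndarray, patch: int) -> np.ndarray:
    """(H, W, 3) float image -> (n_patches, patch*patch*3) rows."""
    H, W, _ = image.shape
    gh, gw = H // patch, W // patch
    x = image.reshape(gh, patch, gw, patch, 3)
    return x.transpose(0, 2, 1, 3, 4).reshape(gh * gw, patch * patch * 3)


def _as_float_image(tile: np.ndarray) -> np.ndarray:
    img = np.asarray(tile, dtype=np.float64)
    if img.max() > 1.5:
        img = img / 255.0
    return img


def _backbone_features(params: dict, cfg: EncoderConfig, tile: np.ndarray) -> Tensor:
    """CLS embedding of one tile mapped to the d-dim feature space."""
    tokens = Tensor(_patchify(_as_float_image(tile), cfg.patch_size))
    x = tokens @ params["embed.w"] + params["embed.b"]
    x = nn.concat([params["cls"], x], axis=0)
    for i in range(cfg.n_layers):
        x = transformer_layer(params, f"layer{i}", x, cfg.n_heads)
    x = nn.layer_norm(x, params["ln_f.g"], params["ln_f.b"])
    cls = x[0:1, :]
    return cls @ params["feat.w"] + params["feat.b"]          # (1, d)


def _project(params: dict, feat: Tensor) -> Tensor:
    h = (feat @ params["proj1.w"] + params["proj1.b"]).relu()
    return h @ params["proj2.w"] + params["proj2.b"]


def _predict(params: dict, z: Tensor) -> Tensor:
    h = (z @ params["pred1.w"] + params["pred1.b"]).relu()
    return h @ params["pred2.w"] + params["pred2.b"]


def _l2_normalize(z: Tensor) -> Tensor:
    norm = (z * z).sum(axis=-1, keepdims=True).sqrt()
    return z / (norm + 1e-12)


# ---------------------------------------------------------------------------
# operations
# ---------------------------------------------------------------------------

def sample_pretraining_tiles(tilesets, per_slide: int = 20, seed: int = 0):
    """Sample up to ``per_slide`` tile coordinates per slide, without
    replacement, seed-deterministically. Returns (slide_id, x, y) triples;
    empty tile sets are skipped with a warning."""
    if per_slide < 1:
        raise ValueError("per_slide must be >= 1")
    rng = np.random.default_rng(seed)
    out = []
    for ts in tilesets:
        n = len(ts)
        if n == 0:
            warnings.warn(f"slide {ts.slide_id!r} has no tiles; skipped")
            continue
        take = min(per_slide, n)
        for i in sorted(rng.choice(n, size=take, replace=False).tolist()):
            out.append((ts.slide_id, int(ts.coords[i, 0]), int(ts.coords[i, 1])))
    return out


def augment_pair(tile: np.ndarray, seed: int, crop_scale: float = 0.4,
                 jitter: float = 0.4, flip_prob: float = 0.5):
    """Two independently augmented views of one tile (random resized crop,
    flips, brightness/contrast jitter). All strengths at 0 return the tile
    itself, bit-exactly, for both views."""
    img = _as_float_image(tile)
    rng = np.random.default_rng(seed)

    def one_view():
        out = img
        if crop_scale > 0:
            scale = rng.uniform(1.0 - crop_scale, 1.0)
            ch = max(1, int(round(img.shape[0] * scale)))
            cw = max(1, int(round(img.shape[1] * scale)))
            y0 = rng.integers(0, img.shape[0] - ch + 1)
            x0 = rng.integers(0, img.shape[1] - cw + 1)
            crop = img[y0:y0 + ch, x0:x0 + cw]
            out = sk_transform.resize(crop, img.shape, anti_aliasing=False,
                                      preserve_range=True)
        if flip_prob > 0:
            if rng.random() < flip_prob:
                out = out[:, ::-1]
            if rng.random() < flip_prob:
                out = out[::-1, :]
        if jitter > 0:
            brightness = rng.uniform(-jitter, jitter)
            contrast = 1.0 + rng.uniform(-jitter, jitter)
            out = np.clip((out - 0.5) * contrast + 0.5 + brightness, 0.0, 1.0)
        return np.ascontiguousarray(out)

    return one_view(), one_view()


def momentum_update(key_params: dict, query_params: dict, m: float) -> dict:
    """In-place EMA: each key parameter <- m * key + (1 - m) * query."""
    if not (0.0 <= m <= 1.0):
        raise ValueError("m must lie in [0, 1]")
    if set(key_params) != set(query_params):
        raise ValueError("parameter sets are not congruent")
    for name, kp in key_params.items():
        qd = query_params[name].data
        if kp.data.shape != qd.shape:
            raise ValueError(f"shape mismatch for parameter {name!r}")
        kp.data = m * kp.data + (1.0 - m) * qd
    return key_params


def contrastive_loss(queries, keys, tau: float = 0.2):
    """InfoNCE over in-batch negatives.

    ``queries`` and ``keys`` are (B, d) with L2-normalized rows; row i of
    the keys is the positive for row i of the queries. Returns the mean of
    -log[ exp(q_i.k_i / tau) / sum_j exp(q_i.k_j / tau) ]. Accepts numpy
    arrays (returns a float) or Tensors (returns a Tensor on the graph).
    """
    if tau <= 0:
        raise ValueError("tau must be > 0")
    q = queries if isinstance(queries, Tensor) else Tensor(np.asarray(queries))
    k = keys if isinstance(keys, Tensor) else Tensor(np.asarray(keys))
    B = q.shape[0]
    if B < 2:
        raise ValueError("need at least 2 pairs for in-batch negatives")
    sim = (q @ k.transpose((1, 0))) * (1.0 / tau)             # (B, B)
    shift = nn.constant(sim.data.max(axis=1, keepdims=True))
    lse = ((sim - shift).exp().sum(axis=1, keepdims=True)).log() + shift
    diag = sim[np.arange(B), np.arange(B)]
    loss = (lse.reshape(B) - diag).mean()
    if isinstance(queries, Tensor) or isinstance(keys, Tensor):
        return loss
    return float(loss.data)


def build_encoder(config: EncoderConfig) -> EncoderState:
    """Fresh dual-encoder state; key parameters start as a copy of the
    query parameters and are flagged non-trainable."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    query = _init_backbone(rng, config, trainable=True)
    key = {name: nn.Tensor(t.data.copy()) for name, t in query.items()}
    return EncoderState(config=config, query_params=query, key_params=key)


def pretrain_encoder(tiles, config: EncoderConfig) -> EncoderState:
    """Momentum-contrast pretraining on a pool of tiles.

    Each step draws a batch, augments every tile into two views, embeds
    view 1 with the query encoder (through the prediction head) and view 2
    with the key encoder, takes one Adam step on the InfoNCE loss and then
    moves the key encoder by the momentum EMA. The per-step loss trace is
    stored on the returned state.
    """
    config.validate()
    tiles = list(tiles)
    if len(tiles) < 2:
        raise ValueError("need at least 2 tiles")
    state = build_encoder(config)
    rng = np.random.default_rng(config.seed + 1)
    opt = nn.Adam(state.query_params, lr=config.lr)
    B = min(config.batch_size, len(tiles))
    for step in range(config.steps):
        idx = rng.choice(len(tiles), size=B, replace=False)
        qs, ks = [], []
        for j in idx:
            v1, v2 = augment_pair(tiles[j], seed=int(rng.integers(2 ** 31)))
            feat_q = _backbone_features(state.query_params, config, v1)
            z_q = _predict(state.query_params,
                           _project(state.query_params, feat_q))
            qs.append(_l2_normalize(z_q))
            feat_k = _backbone_features(state.key_params, config, v2)
            ks.append(_l2_normalize(_project(state.key_params, feat_k)))
        loss = contrastive_loss(nn.concat(qs, axis=0), nn.concat(ks, axis=0),
                                config.tau)
        opt.zero_grad()
        loss.backward()
        opt.step()
        momentum_update(state.key_params, state.query_params, config.momentum)
        state.loss_trace.append(float(loss.data))
    return state


def encode_tiles(encoder: EncoderState, tiles, coords=None,
                 slide_id: str = "", batch: int = 32) -> FeatureBag:
    """Deterministic feature extraction through the query backbone.

    Tiles are processed independently (no batch interactions), so the
    result is identical for any batch size; ``batch`` exists only for API
    symmetry with streaming extraction. Row order follows tile order.
    """
    cfg = encoder.config
    feats = np.zeros((len(tiles), cfg.d))
    for i, tile in enumerate(tiles):
        feats[i] = _backbone_features(encoder.query_params, cfg, tile).data[0]
    if coords is None:
        coords = np.zeros((len(tiles), 2), dtype=np.int64)
    return FeatureBag(slide_id=slide_id, features=feats, coords=coords)
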