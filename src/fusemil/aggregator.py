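"""Transformer feature aggregation: feature bag -> slide-level probability.

A bag of n_tiles x d_in tile features is projected to d_model, a learned
CLS token is prepended, and the sequence passes through a stack of
pre-norm transformer encoder layers (multi-head self-attention + MLP, no
positional encodings — a bag is an unordered set, so the slide logit is
permutation invariant). An MLP head on the final CLS embedding produces
one logit; every layer's row-stochastic attention matrices are exposed
for rollout-based interpretation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import nn
from .nn import Tensor


@dataclass
class AggregatorConfig:
    d_in: int = 384
    d_model: int = 512
    n_layers: int = 2
    n_heads: int = 8
    d_ff: int = 1024
    head_hidden: int = 512
    dropout: float = 0.0
    seed: int = 0

    def validate(self):
        if self.d_model % self.n_heads != 0:
            raise ValueError("d_model must be divisible by n_heads")


@dataclass
class BagForwardOutput:
    logit: float
    probability: float
    attention: np.ndarray      # (n_layers, n_heads, T, T), rows sum to 1
    cls_embedding: np.ndarray


def init_transformer_layer(rng, params: dict, prefix: str, d_model: int, d_ff: int):
    """Allocate one pre-norm encoder layer's parameters into ``params``."""
    for name in ("q", "k", "v", "o"):
        w, b = nn.init_linear(rng, d_model, d_model)
        params[f"{prefix}.{name}.w"], params[f"{prefix}.{name}.b"] = w, b
    params[f"{prefix}.ln1.g"] = nn.parameter(np.ones(d_model))
    params[f"{prefix}.ln1.b"] = nn.parameter(np.zeros(d_model))
    params[f"{prefix}.ln2.g"] = nn.parameter(np.ones(d_model))
    params[f"{prefix}.ln2.b"] = nn.parameter(np.zeros(d_model))
    w, b = nn.init_linear(rng, d_model, d_ff)
    params[f"{prefix}.ff1.w"], params[f"{prefix}.ff1.b"] = w, b
    w, b = nn.init_linear(rng, d_ff, d_model)
    params[f"{prefix}.ff2.w"], params[f"{prefix}.ff2.b"] = w, b


def transformer_layer(params: dict, prefix: str, x: Tensor, n_heads: int,
                      attn_sink: list | None = None) -> Tensor:
    """Pre-norm multi-head self-attention + MLP block on a (T, d_model)
    token sequence; optionally records the row-stochastic attention."""
    T, d_model = x.shape
    h, hd = n_heads, d_model // n_heads
    xn = nn.layer_norm(x, params[f"{prefix}.ln1.g"], params[f"{prefix}.ln1.b"])

    def heads(name):
        y = xn @ params[f"{prefix}.{name}.w"] + params[f"{prefix}.{name}.b"]
        return y.reshape(T, h, hd).transpose((1, 0, 2))

    q, k, v = heads("q"), heads("k"), heads("v")
    scores = (q @ k.transpose((0, 2, 1))) * (1.0 / np.sqrt(hd))
    attn = nn.softmax(scores, axis=-1)           # (h, T, T)
    if attn_sink is not None:
        attn_sink.append(attn.data.copy())
    ctx = (attn @ v).transpose((1, 0, 2)).reshape(T, d_model)
    x = x + (ctx @ params[f"{prefix}.o.w"] + params[f"{prefix}.o.b"])

    xn2 = nn.layer_norm(x, params[f"{prefix}.ln2.g"], params[f"{prefix}.ln2.b"])
    ff = (xn2 @ params[f"{prefix}.ff1.w"] + params[f"{prefix}.ff1.b"]).relu()
    return x + (ff @ params[f"{prefix}.ff2.w"] + params[f"{prefix}.ff2.b"])


class Aggregator:
    """The MIL model: a dict of named parameter Tensors plus the forward."""

    def __init__(self, config: AggregatorConfig):
        config.validate()
        self.config = config
        rng = np.random.default_rng(config.seed)
        c = config
        p = {}
        p["proj.w"], p["proj.b"] = nn.init_linear(rng, c.d_in, c.d_model)
        p["cls"] = nn.parameter(rng.normal(0.0, 0.02, size=(1, c.d_model)))
        for i in range(c.n_layers):
            init_transformer_layer(rng, p, f"layer{i}", c.d_model, c.d_ff)
        p["ln_f.g"] = nn.parameter(np.ones(c.d_model))
        p["ln_f.b"] = nn.parameter(np.zeros(c.d_model))
        w, b = nn.init_linear(rng, c.d_model, c.head_hidden)
        p["head1.w"], p["head1.b"] = w, b
        w, b = nn.init_linear(rng, c.head_hidden, 1)
        p["head2.w"], p["head2.b"] = w, b
        self.params = p

    def forward_logit(self, features: np.ndarray):
        """Forward pass returning (logit Tensor, attention array, cls)."""
        feats = np.asarray(features, dtype=np.float64)
        if feats.ndim != 2 or feats.shape[0] < 1:
            raise ValueError("bag must contain at least one tile")
        if feats.shape[1] != self.config.d_in:
            raise ValueError(
                f"bag feature dim {feats.shape[1]} != configured d_in {self.config.d_in}")
        p = self.params
        x = Tensor(feats) @ p["proj.w"] + p["proj.b"]
        x = nn.concat([p["cls"], x], axis=0)
        attn_sink = []
        for i in range(self.config.n_layers):
            x = transformer_layer(p, f"layer{i}", x, self.config.n_heads, attn_sink)
        x = nn.layer_norm(x, p["ln_f.g"], p["ln_f.b"])
        cls = x[0:1, :]
        hid = (cls @ p["head1.w"] + p["head1.b"]).relu()
        logit = (hid @ p["head2.w"] + p["head2.b"]).reshape(())
        return logit, np.stack(attn_sink), cls.data.copy()


def build_aggregator(config: AggregatorConfig) -> Aggregator:
    """Seed-deterministic model construction."""
    return Aggregator(config)


def parameter_count(config: AggregatorConfig) -> int:
    """Closed-form parameter count for a configured model."""
    c = config
    n = c.d_in * c.d_model + c.d_model          # projection
    n += c.d_model                              # CLS token
    per_layer = 4 * (c.d_model * c.d_model + c.d_model)   # q,k,v,o
    per_layer += 4 * c.d_model                  # two layer norms
    per_layer += c.d_model * c.d_ff + c.d_ff
    per_layer += c.d_ff * c.d_model + c.d_model
    n += c.n_layers * per_layer
    n += 2 * c.d_model                          # final norm
    n += c.d_model * c.head_hidden + c.head_hidden
    n += c.head_hidden * 1 + 1
    return n


def forward_bag(model: Aggregator, bag) -> BagForwardOutput:
    """Inference on one bag; returns logit, probability and all attention.

    ``bag`` may be a FeatureBag, anything with a ``features`` attribute,
    or a bare (n_tiles, d) array.
    """
    features = getattr(bag, "features", bag)
    logit, attn, cls = model.forward_logit(features)
    z = float(logit.data)
    return BagForwardOutput(logit=z, probability=float(1.0 / (1.0 + np.exp(-z))),
                            attention=attn, cls_embedding=cls)


def tile_scores(model: Aggregator, bag) -> np.ndarray:
    """Per-tile probabilities via the singleton-bag pathway: tile i's score
    is the model's output on the bag containing only tile i."""
    features = np.asarray(getattr(bag, "features", bag))
    return np.array([
        forward_bag(model, features[i:i + 1]).probability
        for i in range(features.shape[0])
    ])
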