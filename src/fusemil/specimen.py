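"""Thumbnail-level biopsy-vs-resection classification.

Specimen type is a coarse morphological property — several small scattered
fragments (biopsy) versus one large contiguous region (resection) — so a
small convolutional network on slide thumbnails suffices. Thumbnails are
resized to 224 x 224; training uses cross-entropy, Adam at learning rate
0.001, batch size 32 and 25 epochs by default, with flip/rotation/jitter
augmentation. The backbone is pluggable; the default is a two-conv-layer
network sized for desk-scale fixtures (a VGG-class stack drops in through
the same parameter-dict interface).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from skimage import transform as sk_transform

from . import nn
from .nn import Tensor

CLASSES = ("biopsy", "resection")


@dataclass
class SpecimenConfig:
    input_size: int = 224
    channels: tuple = (8, 16)      # conv channels of the tiny backbone
    lr: float = 0.001
    batch_size: int = 32
    epochs: int = 25
    augment: bool = True
    seed: int = 0


class SpecimenModel:
    """Tiny CNN: fixed 4x average pool, two 3x3 conv+relu stages with 2x
    pooling, global average pool, linear softmax head."""

    def __init__(self, config: SpecimenConfig):
        self.config = config
        rng = np.random.default_rng(config.seed)
        c1, c2 = config.channels
        p = {}
        p["conv1.w"], p["conv1.b"] = nn.init_linear(rng, 9 * 3, c1)
        p["conv2.w"], p["conv2.b"] = nn.init_linear(rng, 9 * c1, c2)
        p["fc.w"], p["fc.b"] = nn.init_linear(rng, c2, 2)
        self.params = p

    def forward(self, images: np.ndarray) -> Tensor:
        """(B, 224, 224, 3) float batch -> (B, 2) logits."""
        x = Tensor(np.asarray(images, dtype=np.float64))
        x = nn.avg_pool2d(x, 4)                       # 56x56
        x = nn.conv2d(x, self.params["conv1.w"], self.params["conv1.b"]).relu()
        x = nn.avg_pool2d(x, 2)                       # 28x28
        x = nn.conv2d(x, self.params["conv2.w"], self.params["conv2.b"]).relu()
        x = nn.avg_pool2d(x, 2)                       # 14x14
        x = x.mean(axis=(1, 2))                       # (B, c2)
        return x @ self.params["fc.w"] + self.params["fc.b"]


def _prep_image(image: np.ndarray, size: int) -> np.ndarray:
    """Scale to [0,1], resize to the model input size and invert so the
    near-white background maps to ~0 — global average pooling then sees
    tissue rather than background."""
    img = np.asarray(image, dtype=np.float64)
    if img.max() > 1.5:
        img = img / 255.0
    if img.shape[:2] != (size, size):
        warnings.warn("thumbnail resized to the configured input size")
        img = sk_transform.resize(img, (size, size, 3), anti_aliasing=True,
                                  preserve_range=True)
    return 1.0 - img


def _augment(img: np.ndarray, rng) -> np.ndarray:
    if rng.random() < 0.5:
        img = img[:, ::-1]
    if rng.random() < 0.5:
        img = img[::-1, :]
    img = np.rot90(img, k=int(rng.integers(0, 4)))
    jitter = rng.uniform(-0.1, 0.1)
    return np.clip(img + jitter, 0.0, 1.0)


def _cross_entropy(logits: Tensor, y: np.ndarray) -> Tensor:
    B = logits.shape[0]
    shift = nn.constant(logits.data.max(axis=1, keepdims=True))
    lse = ((logits - shift).exp().sum(axis=1, keepdims=True)).log() + shift
    picked = logits[np.arange(B), y]
    return (lse.reshape(B) - picked).mean()


def train_specimen_classifier(thumbnails, labels, config: SpecimenConfig | None = None):
    """Train the two-class thumbnail model; returns (model, accuracy trace).

    ``labels`` are "biopsy"/"resection" strings; both classes must be
    present. Seed-deterministic; learning rate 0 leaves the parameters (and
    so the accuracy trace) unchanged.
    """
    config = config or SpecimenConfig()
    labels = np.asarray(labels)
    y = np.array([CLASSES.index(l) for l in labels])
    if len(set(y.tolist())) < 2:
        raise ValueError("both specimen classes must be present")
    images = np.stack([_prep_image(t, config.input_size) for t in thumbnails])

    model = SpecimenModel(config)
    rng = np.random.default_rng(config.seed + 1)
    opt = nn.Adam(model.params, lr=config.lr)
    trace = []
    for _ in range(config.epochs):
        order = rng.permutation(len(y))
        correct = 0
        for start in range(0, len(order), config.batch_size):
            idx = order[start:start + config.batch_size]
            batch = images[idx]
            if config.augment:
                batch = np.stack([_augment(im, rng) for im in batch])
            logits = model.forward(batch)
            loss = _cross_entropy(logits, y[idx])
            opt.zero_grad()
            loss.backward()
            opt.step()
            correct += int(np.sum(np.argmax(logits.data, axis=1) == y[idx]))
        trace.append(correct / len(y))
    return model, trace


def predict_specimen(model: SpecimenModel, thumbnail) -> tuple:
    """Inference (no augmentation): argmax class and its softmax probability."""
    img = _prep_image(thumbnail, model.config.input_size)
    logits = model.forward(img[None]).data[0]
    z = logits - logits.max()
    probs = np.exp(z) / np.exp(z).sum()
    idx = int(np.argmax(probs))
    return CLASSES[idx], float(probs[idx])
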