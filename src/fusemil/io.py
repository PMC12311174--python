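"""File formats: HDF5 feature-bag containers, CSV manifests/tilesets,
PNG/TIFF images and npz checkpoints."""

from __future__ import annotations

import json

import h5py
import numpy as np
import pandas as pd
from PIL import Image

from .aggregator import Aggregator, AggregatorConfig
from .synthetic import FeatureBag
from .tissue import TileSet


# ---------------------------------------------------------------------------
# bag container: one group per slide with `features` and `coords`
# ---------------------------------------------------------------------------

def write_bags(path, bags, tile_size: int = 224, magnification: float = 10.0):
    with h5py.File(path, "w") as f:
        for bag in bags:
            g = f.create_group(bag.slide_id)
            g.create_dataset("features", data=bag.features)
            g.create_dataset("coords", data=bag.coords)
            g.attrs["d"] = bag.d
            g.attrs["tile_size"] = tile_size
            g.attrs["magnification"] = magnification


def read_bags(path) -> dict:
    out = {}
    with h5py.File(path, "r") as f:
        for sid in f:
            out[sid] = FeatureBag(slide_id=sid,
                                  features=f[sid]["features"][...],
                                  coords=f[sid]["coords"][...])
    return out


# ---------------------------------------------------------------------------
# manifests and tilesets
# ---------------------------------------------------------------------------

def write_manifest(path, manifest: pd.DataFrame):
    manifest.to_csv(path, index=False)


def read_manifest(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    for col in ("ROS1", "ALK", "NTRK", "RAN"):
        if col in df.columns:
            df[col] = df[col].astype(bool)
    return df


def write_tileset(path, tileset: TileSet):
    pd.DataFrame({
        "slide_id": tileset.slide_id,
        "x": tileset.coords[:, 0],
        "y": tileset.coords[:, 1],
        "tile_size": tileset.tile_size,
    }).to_csv(path, index=False)


def read_tileset(path) -> TileSet:
    df = pd.read_csv(path)
    return TileSet(slide_id=str(df["slide_id"].iloc[0]) if len(df) else "",
                   tile_size=int(df["tile_size"].iloc[0]) if len(df) else 224,
                   magnification=10.0,
                   coords=df[["x", "y"]].to_numpy() if len(df) else np.zeros((0, 2)))


# ---------------------------------------------------------------------------
# images
# ---------------------------------------------------------------------------

def write_image(path, image: np.ndarray):
    img = np.asarray(image)
    if img.dtype != np.uint8:
        img = np.clip(np.round(img * 255.0 if img.max() <= 1.5 else img), 0, 255)
        img = img.astype(np.uint8)
    Image.fromarray(img).save(path)


def read_image(path) -> np.ndarray:
    return np.asarray(Image.open(path))


# ---------------------------------------------------------------------------
# checkpoints
# ---------------------------------------------------------------------------

def save_encoder(path, state):
    from .encoder import EncoderState  # noqa: F401  (type reference)
    arrays = {}
    for prefix, params in (("q", state.query_params), ("k", state.key_params)):
        for name, t in params.items():
            arrays[f"{prefix}::{name}"] = t.data
    arrays["__config__"] = np.frombuffer(
        json.dumps(state.config.__dict__).encode(), dtype=np.uint8)
    np.savez(path, **arrays)


def load_encoder(path):
    from .encoder import EncoderConfig, build_encoder
    with np.load(path) as z:
        cfg = EncoderConfig(**json.loads(bytes(z["__config__"]).decode()))
        state = build_encoder(cfg)
        for prefix, params in (("q", state.query_params), ("k", state.key_params)):
            for name, t in params.items():
                t.data = z[f"{prefix}::{name}"].copy()
    return state


def save_aggregator(path, model: Aggregator):
    arrays = {name: t.data for name, t in model.params.items()}
    arrays["__config__"] = np.frombuffer(
        json.dumps(model.config.__dict__).encode(), dtype=np.uint8)
    np.savez(path, **arrays)


def load_aggregator(path) -> Aggregator:
    with np.load(path) as z:
        cfg = AggregatorConfig(**json.loads(bytes(z["__config__"]).decode()))
        model = Aggregator(cfg)
        for name, t in model.params.items():
            t.data = z[name].copy()
    return model
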