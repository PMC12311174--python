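"""Label composition, holdout carving, stratified splits and downsampling.

The composite RAN label marks a slide positive if it harbors any ROS1, ALK
or NTRK fusion. An independent holdout fraction is reserved before any
training; the remainder (the CV set) is divided into k independent
stratified 60/20/20 train/validation/test draws, and each fold's training
negatives are downsampled to a fixed multiple of its positives.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

FUSION_COLUMNS = ("ROS1", "ALK", "NTRK")


@dataclass
class Fold:
    train_ids: list
    val_ids: list
    test_ids: list
    downsampled_train_ids: list = field(default_factory=list)


@dataclass
class SplitPlan:
    holdout_ids: list
    folds: list
    seed: int
    stratify_label: str = "RAN"

    def to_json(self, path):
        payload = {
            "holdout_ids": list(self.holdout_ids),
            "folds": [asdict(f) for f in self.folds],
            "seed": self.seed,
            "stratify_label": self.stratify_label,
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1)

    @classmethod
    def from_json(cls, path):
        with open(path) as fh:
            payload = json.load(fh)
        return cls(holdout_ids=payload["holdout_ids"],
                   folds=[Fold(**f) for f in payload["folds"]],
                   seed=payload["seed"],
                   stratify_label=payload["stratify_label"])


def compose_ran_label(table: pd.DataFrame) -> pd.DataFrame:
    """Add the composite RAN column: logical OR of the three fusion labels."""
    for col in FUSION_COLUMNS:
        if col not in table.columns:
            raise ValueError(f"missing fusion column {col}")
        missing = table[col].isna()
        if missing.any():
            sid = table.loc[missing, "slide_id"].iloc[0]
            raise ValueError(f"missing {col} value for slide_id {sid!r}")
    out = table.copy()
    out["RAN"] = out[list(FUSION_COLUMNS)].astype(bool).any(axis=1)
    return out


def make_holdout(table: pd.DataFrame, frac: float = 0.15, seed: int = 0):
    """Reserve ``round(frac * n)`` slides as the holdout set.

    Returns ``(cv_ids, holdout_ids)`` — a random, seed-deterministic,
    disjoint and exhaustive partition of the slide ids.
    """
    if not (0.0 < frac < 1.0):
        raise ValueError("frac must lie in (0, 1)")
    ids = table["slide_id"].tolist()
    if len(ids) < 2:
        raise ValueError("need at least 2 slides to carve a holdout")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(len(ids))
    n_hold = int(round(frac * len(ids)))
    holdout = [ids[i] for i in perm[:n_hold]]
    cv = [ids[i] for i in perm[n_hold:]]
    return cv, holdout


def _largest_remainder(total: int, fractions) -> np.ndarray:
    """Integer allocation of ``total`` by largest remainder; sums exactly."""
    raw = np.asarray(fractions, dtype=float) * total
    base = np.floor(raw).astype(int)
    short = total - base.sum()
    order = np.argsort(-(raw - base))
    base[order[:short]] += 1
    return base


def make_cv_splits(cv_table: pd.DataFrame, k: int = 5,
                   fractions=(0.6, 0.2, 0.2), stratify: str = "RAN",
                   seed: int = 0) -> list:
    """k independent stratified train/val/test draws (not a k-fold partition).

    Per draw, each class is allocated to the three sets by largest-remainder
    rounding of the fractions, so class proportions match the targets to
    within one sample. ``stratify`` may name any categorical column; with
    the default boolean RAN column this is plain two-class stratification.
    """
    if abs(sum(fractions) - 1.0) > 1e-9:
        raise ValueError("fractions must sum to 1")
    y = cv_table[stratify].to_numpy()
    ids = cv_table["slide_id"].to_numpy()
    classes = [ids[y == v] for v in pd.unique(y)]
    if len(classes) < 2:
        raise ValueError("at least two classes must be present for stratification")
    if min(len(c) for c in classes) < k:
        warnings.warn("a class has fewer samples than the number of splits")
    rng = np.random.default_rng(seed)
    folds = []
    for _ in range(k):
        parts = ([], [], [])
        for cls_ids in classes:
            perm = rng.permutation(len(cls_ids))
            counts = _largest_remainder(len(cls_ids), fractions)
            offsets = np.concatenate([[0], np.cumsum(counts)])
            for j in range(3):
                parts[j].extend(cls_ids[perm[offsets[j]:offsets[j + 1]]].tolist())
        folds.append(Fold(train_ids=parts[0], val_ids=parts[1], test_ids=parts[2]))
    return folds


def downsample_negatives(train_ids, labels: pd.Series, ratio: float = 5,
                         seed: int = 0) -> list:
    """Keep all positives and sample negatives without replacement down to
    ``min(N, ratio * P)``; seed-deterministic."""
    if ratio <= 0:
        raise ValueError("ratio must be > 0")
    lab = labels.loc[train_ids].astype(bool)
    pos = [i for i in train_ids if lab[i]]
    neg = [i for i in train_ids if not lab[i]]
    if not pos:
        raise ValueError("training set has no positive samples")
    rng = np.random.default_rng(seed)
    n_keep = min(len(neg), int(ratio * len(pos)))
    kept = [neg[i] for i in rng.permutation(len(neg))[:n_keep]]
    return pos + kept


def build_split_plan(table: pd.DataFrame, holdout_frac: float = 0.15, k: int = 5,
                     fractions=(0.6, 0.2, 0.2), stratify: str = "RAN",
                     downsample_ratio: float = 5, seed: int = 0) -> SplitPlan:
    """Full planning pass: RAN composition, holdout carve, k stratified
    splits, per-fold negative downsampling."""
    table = compose_ran_label(table)
    cv_ids, holdout_ids = make_holdout(table, holdout_frac, seed)
    cv_table = table[table["slide_id"].isin(cv_ids)]
    folds = make_cv_splits(cv_table, k=k, fractions=fractions,
                           stratify=stratify, seed=seed + 1)
    labels = table.set_index("slide_id")[stratify]
    for j, fold in enumerate(folds):
        fold.downsampled_train_ids = downsample_negatives(
            fold.train_ids, labels, ratio=downsample_ratio, seed=seed + 100 + j)
    return SplitPlan(holdout_ids=holdout_ids, folds=folds, seed=seed,
                     stratify_label=stratify)
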