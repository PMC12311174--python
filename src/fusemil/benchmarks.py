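"""Desk-scale benchmark harnesses exercising the full pipeline end to end.

Each harness wires the synthetic generators to the training / evaluation
stack under one fixed set of study conditions: three mutually exclusive
rare fusion sub-labels (target prevalence 1%), a shared fusion signal at
least as strong as the sub-label-specific one, 5:1 negative downsampling
and a positive class weight of 5 unless swept. Problem sizes are chosen so
a single CPU traverses each harness in minutes; the harnesses measure
directions and contracts (transfer benefit, weight trade-off, mask
recovery, specimen separability), not the clinical-scale operating points.
"""

from __future__ import annotations

import numpy as np

from .aggregator import AggregatorConfig
from .cohorts import compose_ran_label, downsample_negatives, make_cv_splits
from .evaluation import summary_metrics
from .synthetic import (SynthBagSpec, SynthSlideSpec, gen_bag_dataset,
                        gen_specimen_thumbnails, gen_synthetic_slide,
                        random_slide_spec)
from .tissue import build_tissue_mask, tile_slide
from .training import TrainConfig, select_checkpoint, train_direct, train_finetune

TINY_AGG = dict(d_in=16, d_model=32, n_layers=2, n_heads=8, d_ff=64,
                head_hidden=32)


def make_bag_benchmark(seed: int, n_slides: int = 800, **overrides):
    """Synthetic bag dataset + one stratified fold, ready for training.

    Returns ``(bags_by_id, table, fold)``. The fold is stratified on the
    joint fusion category (ROS1 / ALK / NTRK / negative) so that at desk
    scale every subset holds at least one positive of each rare sub-label
    — with a binary RAN stratification and only a handful of target
    positives, a validation set can otherwise end up single-class. The
    fold carries no downsampled list; build one per training label with
    :func:`fold_for_label`.
    """
    spec = SynthBagSpec(n_slides=n_slides, seed=seed, **overrides)
    bags, manifest = gen_bag_dataset(spec)
    table = compose_ran_label(manifest)
    table["fusion_cat"] = np.select(
        [table["ROS1"], table["ALK"], table["NTRK"]],
        ["ROS1", "ALK", "NTRK"], default="neg")
    fold = make_cv_splits(table, k=1, stratify="fusion_cat", seed=seed + 1)[0]
    bags_by_id = {b.slide_id: b for b in bags}
    return bags_by_id, table, fold


def fold_for_label(fold, table, label: str, seed: int, ratio: float = 5):
    """Copy of the fold with training negatives downsampled ``ratio``:1
    against ``label`` positives; validation and test sets are untouched."""
    from dataclasses import replace
    labels = table.set_index("slide_id")[label]
    ds = downsample_negatives(fold.train_ids, labels, ratio=ratio, seed=seed)
    return replace(fold, downsampled_train_ids=ds)


def _label_map(table, column):
    return table.set_index("slide_id")[column].astype(int).to_dict()


def transfer_benchmark(seeds, target: str = "ROS1", n_slides: int = 800,
                       epochs: int = 35, ft_epochs: int = 10):
    """Direct vs composite-pretrain/fine-tune, per seed.

    Returns ``(direct_aucs, finetune_aucs)``: the selected validation AUC of
    each strategy for each seed, the comparison behind the two-step
    training rationale.
    """
    direct_aucs, finetune_aucs = [], []
    for seed in seeds:
        bags, table, fold = make_bag_benchmark(seed, n_slides=n_slides)
        ran = _label_map(table, "RAN")
        tgt = _label_map(table, target)
        agg = AggregatorConfig(seed=seed, **TINY_AGG)
        fold_tgt = fold_for_label(fold, table, target, seed + 2)
        fold_ran = fold_for_label(fold, table, "RAN", seed + 3)

        cfg_direct = TrainConfig(target_label=target, epochs=epochs, seed=seed)
        _, tr_direct = train_direct(bags, fold_tgt, tgt, cfg_direct, agg)
        direct_aucs.append(max(tr_direct.val_auc))

        cfg_ran = TrainConfig(target_label="RAN", epochs=epochs, seed=seed)
        cfg_ft = TrainConfig(target_label=target, epochs=ft_epochs, seed=seed)
        _, _, tr_ft = train_finetune(bags, fold_ran, ran, tgt, cfg_ran, cfg_ft,
                                     agg, target_fold=fold_tgt)
        finetune_aucs.append(max(tr_ft.val_auc))
    return np.array(direct_aucs), np.array(finetune_aucs)


def weight_sweep(seeds, weights=(5, 10, 20, 30), n_slides: int = 800,
                 epochs: int = 20):
    """Positive-weight sweep on the composite label, test-set metrics.

    Returns a dict W -> list of MetricsReport (one per seed); the trade-off
    pattern is PPA rising and accuracy/NPA falling as W grows, with ROC AUC
    nearly flat.
    """
    out = {w: [] for w in weights}
    for seed in seeds:
        bags, table, base_fold = make_bag_benchmark(seed, n_slides=n_slides)
        ran = _label_map(table, "RAN")
        agg = AggregatorConfig(seed=seed, **TINY_AGG)
        fold = fold_for_label(base_fold, table, "RAN", seed + 2)
        for w in weights:
            cfg = TrainConfig(target_label="RAN", pos_weight=float(w),
                              epochs=epochs, seed=seed)
            model, _ = train_direct(bags, fold, ran, cfg, agg)
            scores = np.array([
                1.0 / (1.0 + np.exp(-model.forward_logit(bags[i].features)[0].data))
                for i in fold.test_ids])
            y = np.array([ran[i] for i in fold.test_ids])
            out[w].append(summary_metrics(scores, y))
    return out


def mask_benchmark(seeds):
    """Mask recovery on random synthetic slides.

    Returns ``(jaccards, overlaps)``: per-seed Jaccard of the final mask
    against the artifact-free planted tissue, and a dict artifact-class ->
    per-seed overlap fraction of the planted region retained by the mask.
    """
    jaccards, overlaps = [], {"blur": [], "dark": [], "fat": []}
    for seed in seeds:
        img, masks = gen_synthetic_slide(random_slide_spec(seed))
        tm = build_tissue_mask(img, scale=1.0)
        truth = masks["tissue"]
        jaccards.append(float((tm.mask & truth).sum() / (tm.mask | truth).sum()))
        for k in overlaps:
            area = masks[k].sum()
            overlaps[k].append(float((tm.mask & masks[k]).sum() / area) if area else 0.0)
    return np.array(jaccards), {k: np.array(v) for k, v in overlaps.items()}


def specimen_benchmark(seed: int, n: int = 200, epochs: int = 12,
                       holdout_frac: float = 0.25):
    """Train the tiny specimen CNN on a balanced synthetic fixture and
    return its held-out accuracy."""
    from .specimen import SpecimenConfig, predict_specimen, train_specimen_classifier

    images, labels = gen_specimen_thumbnails(n, seed=seed)
    rng = np.random.default_rng(seed + 1)
    perm = rng.permutation(n)
    n_hold = int(round(holdout_frac * n))
    hold, train = perm[:n_hold], perm[n_hold:]
    cfg = SpecimenConfig(epochs=epochs, seed=seed)
    model, _ = train_specimen_classifier(images[train], labels[train], cfg)
    correct = sum(
        predict_specimen(model, images[i])[0] == labels[i] for i in hold)
    return correct / len(hold)
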