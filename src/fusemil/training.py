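"""Class-weighted training of the bag aggregator, direct and two-step.

Rare fusion labels make plain training unstable, so two levers rebalance
the problem: training negatives are downsampled to a fixed multiple of the
positives (see :mod:`fusemil.cohorts`) and the positive term of the binary
cross-entropy carries a weight W (default 5). The two-step procedure first
trains on the composite RAN label (any ROS1/ALK/NTRK fusion), then
fine-tunes the selected checkpoint on the rare target label at a learning
rate ten times smaller — transferring the shared fusion signal learned
from the more plentiful composite positives.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from sklearn.metrics import roc_auc_score

from . import nn
from .aggregator import Aggregator, AggregatorConfig, build_aggregator
from .nn import Tensor

EPS = 1e-12


@dataclass
class TrainConfig:
    target_label: str = "RAN"
    pos_weight: float = 5.0
    lr_direct: float = 1e-3
    finetune_lr_factor: float = 0.1
    epochs: int = 25
    batch_size: int = 4
    eval_every: int = 1          # epochs between validation evaluations
    seed: int = 0

    def validate(self):
        if self.pos_weight <= 0:
            raise ValueError("pos_weight must be > 0")
        if self.finetune_lr_factor <= 0:
            raise ValueError("finetune_lr_factor must be > 0")


@dataclass
class TrainTrace:
    val_auc: list = field(default_factory=list)
    val_steps: list = field(default_factory=list)
    loss: list = field(default_factory=list)
    selected_step: int = -1
    lr: float = 0.0


def weighted_bce(p: float, y: int, w: float = 5.0) -> float:
    """-[w * y * log p + (1-y) * log(1-p)]; w=1 is plain cross-entropy.

    Probabilities outside (0, 1) are clamped with a small epsilon (logged).
    """
    p = float(p)
    if not (0.0 < p < 1.0):
        warnings.warn("probability outside (0,1); clamped")
        p = min(max(p, EPS), 1.0 - EPS)
    y = int(y)
    return -(w * y * np.log(p) + (1 - y) * np.log(1.0 - p))


def _weighted_bce_logit(logit: Tensor, y: int, w: float) -> Tensor:
    """Stable loss on the logit: w*y*softplus(-z) + (1-y)*softplus(z)."""
    if y:
        return nn.softplus(-logit) * w
    return nn.softplus(logit)


def select_checkpoint(trace: TrainTrace) -> int:
    """Index (into the validation trace) of the maximum validation AUC;
    ties break to the earliest step."""
    if not trace.val_auc:
        raise ValueError("empty trace")
    return int(np.argmax(trace.val_auc))


def _val_auc(model: Aggregator, bags_by_id: dict, ids, labels) -> float:
    y = np.array([int(labels[i]) for i in ids])
    if y.sum() == 0 or y.sum() == len(y):
        raise ValueError("validation set contains a single class")
    scores = np.array([
        float(model.forward_logit(bags_by_id[i].features)[0].data) for i in ids])
    return float(roc_auc_score(y, scores))


def _clone_params(params: dict) -> dict:
    return {k: p.data.copy() for k, p in params.items()}


def _train_loop(model: Aggregator, bags_by_id: dict, fold, labels,
                config: TrainConfig, lr: float) -> TrainTrace:
    config.validate()
    train_ids = list(fold.downsampled_train_ids or fold.train_ids)
    y_train = {i: int(labels[i]) for i in train_ids}
    if sum(y_train.values()) in (0, len(train_ids)):
        raise ValueError("downsampled training set must contain both classes")

    rng = np.random.default_rng(config.seed)
    opt = nn.Adam(model.params, lr=lr)
    trace = TrainTrace(lr=lr)
    checkpoints = []
    step = 0
    for epoch in range(config.epochs):
        order = rng.permutation(len(train_ids))
        for start in range(0, len(order), config.batch_size):
            idx = order[start:start + config.batch_size]
            opt.zero_grad()
            batch_loss = 0.0
            for j in idx:
                sid = train_ids[j]
                logit, _, _ = model.forward_logit(bags_by_id[sid].features)
                loss = _weighted_bce_logit(logit, y_train[sid], config.pos_weight)
                loss = loss * (1.0 / len(idx))
                loss.backward()
                batch_loss += float(loss.data) * len(idx)
            opt.step()
            trace.loss.append(batch_loss / len(idx))
            step += 1
        if (epoch + 1) % config.eval_every == 0 or epoch == config.epochs - 1:
            trace.val_auc.append(_val_auc(model, bags_by_id, fold.val_ids, labels))
            trace.val_steps.append(step)
            checkpoints.append(_clone_params(model.params))
    if trace.val_auc:
        best = select_checkpoint(trace)
        trace.selected_step = trace.val_steps[best]
        for k, p in model.params.items():
            p.data = checkpoints[best][k]
    return trace


def train_direct(bags_by_id: dict, fold, labels, config: TrainConfig,
                 agg_config: AggregatorConfig | None = None):
    """Train an aggregator from scratch on ``config.target_label``.

    ``labels`` maps slide_id -> 0/1 for the target label. Returns the model
    restored to its best-validation checkpoint plus the trace.
    """
    if agg_config is None:
        agg_config = AggregatorConfig(seed=config.seed)
    model = build_aggregator(agg_config)
    trace = _train_loop(model, bags_by_id, fold, labels, config, config.lr_direct)
    return model, trace


def train_finetune(bags_by_id: dict, fold, ran_labels, target_labels,
                   ran_config: TrainConfig, target_config: TrainConfig,
                   agg_config: AggregatorConfig | None = None,
                   target_fold=None):
    """Two-step training: RAN stage then target fine-tune at 10x smaller lr.

    Stage 1 trains on the composite labels; the checkpoint with the best
    RAN validation AUC initializes stage 2, which trains on the target
    label at ``lr_direct * finetune_lr_factor`` on the same split (pass
    ``target_fold`` to give stage 2 its own label-matched downsampled
    training list; validation/test ids must agree). Returns
    ``(model, ran_trace, finetune_trace)``; zero fine-tune epochs return
    the stage-1 checkpoint unchanged.
    """
    if agg_config is None:
        agg_config = AggregatorConfig(seed=ran_config.seed)
    model = build_aggregator(agg_config)
    ran_trace = _train_loop(model, bags_by_id, fold, ran_labels,
                            ran_config, ran_config.lr_direct)
    ft_lr = target_config.lr_direct * target_config.finetune_lr_factor
    if target_config.epochs == 0:
        ft_trace = TrainTrace(lr=ft_lr)
        return model, ran_trace, ft_trace
    ft_trace = _train_loop(model, bags_by_id, fold if target_fold is None else target_fold,
                           target_labels, target_config, ft_lr)
    return model, ran_trace, ft_trace
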