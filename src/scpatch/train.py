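"""Training: sparse categorical cross-entropy, cosine LR decay, momentum SGD.

The optimiser is SGD with momentum and *decoupled* weight decay (LayerNorm
parameters and biases are excluded from decay). The learning rate follows a
cosine decline r_t = 0.5 * r0 * (1 + cos(t*pi/T)) over the total step count
T = epochs * batches-per-epoch, floored at ``end_lr``.
"""

from __future__ import annotations

import hashlib
import json
import logging
import warnings
from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd

from . import _autograd as ag
from .io import ExpressionMatrix, LabelMap
from .model import ModelConfig, ModelState, build_model, forward_logits, predict_proba

logger = logging.getLogger(__name__)

_EPS = 1e-12  # probability clip before log


@dataclass
class TrainConfig:
    epochs: int = 50
    batch_size: int = 64
    initial_lr: float = 1e-3
    end_lr: float = 1e-5
    weight_decay: float = 1e-4
    momentum: float = 0.9
    seed: int = 0
    class_weighting: bool = False  # optional inverse-frequency loss weights

    def __post_init__(self):
        if self.epochs < 1 or self.batch_size < 1:
            raise ValueError("epochs and batch_size must be >= 1")
        if self.end_lr > self.initial_lr:
            raise ValueError("end_lr must not exceed initial_lr")

    @classmethod
    def desk_preset(cls, **overrides) -> "TrainConfig":
        """Optimisation scale suited to the small desk model and fixtures."""
        kw = dict(epochs=30, batch_size=32, initial_lr=0.05, end_lr=1e-4,
                  weight_decay=1e-2, momentum=0.9)
        kw.update(overrides)
        return cls(**kw)

    def config_hash(self) -> str:
        return hashlib.sha256(
            json.dumps(asdict(self), sort_keys=True).encode()).hexdigest()[:12]


def cross_entropy_loss(true_labels, predicted: np.ndarray) -> float:
    """Mean over cells of -ln p[y], with p clipped to [1e-12, 1]."""
    y = np.asarray(true_labels, dtype=np.int64)
    p = np.asarray(predicted, dtype=np.float64)
    if y.ndim != 1 or p.ndim != 2 or y.shape[0] != p.shape[0]:
        raise ValueError("need n labels and an n x K probability matrix")
    if np.any(y < 0) or np.any(y >= p.shape[1]):
        raise ValueError("label out of range")
    picked = np.clip(p[np.arange(len(y)), y], _EPS, 1.0)
    return float(-np.log(picked).mean())


def lr_at_step(t: int, cfg: TrainConfig, total_steps: int) -> float:
    """Cosine decay 0.5*r0*(1+cos(t*pi/T)), floored at end_lr."""
    if not 0 <= t <= total_steps:
        raise ValueError(f"step {t} outside [0, {total_steps}]")
    raw = 0.5 * cfg.initial_lr * (1.0 + np.cos(np.pi * t / total_steps))
    return float(max(cfg.end_lr, raw))


def _is_decayed(name: str) -> bool:
    """Decay weight matrices only: not LN params, biases, or embeddings."""
    if ".gamma" in name or ".beta" in name:
        return False
    if name in ("class_token", "pos_table"):
        return False
    return name.rsplit(".", 1)[-1].startswith("w")


def train_model(
    train: ExpressionMatrix,
    model_cfg: ModelConfig,
    train_cfg: TrainConfig,
    reference_genes: list[str] | None = None,
) -> tuple[ModelState, pd.DataFrame]:
    """Fit a model on a labelled, normalised matrix; returns (state, history).

    History has one row per epoch: epoch, loss (mean over batches), train_acc
    (inference-mode pass over the training set at epoch end), lr.
    """
    if train.labels is None:
        raise ValueError("training requires labels")
    if not train.normalized:
        raise ValueError("training expects log-normalised expression")
    label_map = LabelMap.from_labels(sorted(set(train.labels)))
    if len(label_map) < 2:
        raise ValueError("training requires at least 2 classes")
    if len(label_map) != model_cfg.n_classes:
        raise ValueError(
            f"model configured for {model_cfg.n_classes} classes but the "
            f"training labels contain {len(label_map)}")
    y = label_map.encode(train.labels)

    batch_size = train_cfg.batch_size
    if batch_size > train.n_cells:
        warnings.warn("batch_size exceeds cell count; clamping")
        batch_size = train.n_cells
    n_batches = -(-train.n_cells // batch_size)
    total_steps = train_cfg.epochs * n_batches

    state = build_model(train.n_genes, label_map, model_cfg,
                        seed=train_cfg.seed,
                        reference_genes=reference_genes or train.gene_ids)
    rng = np.random.default_rng(train_cfg.seed)
    velocity = {k: np.zeros_like(p.data) for k, p in state.params.items()}

    class_w = None
    if train_cfg.class_weighting:
        counts = np.bincount(y, minlength=len(label_map)).astype(float)
        class_w = counts.sum() / (len(counts) * np.maximum(counts, 1.0))

    logger.info("training: %d cells, %d genes, %d classes, %d steps, config %s",
                train.n_cells, train.n_genes, len(label_map), total_steps,
                train_cfg.config_hash())
    history = []
    step = 0
    for epoch in range(1, train_cfg.epochs + 1):
        order = rng.permutation(train.n_cells)
        epoch_losses = []
        for b in range(n_batches):
            idx = order[b * batch_size:(b + 1) * batch_size]
            logits = forward_logits(train.values[idx], state,
                                    training=True, rng=rng)
            w = class_w[y[idx]] if class_w is not None else None
            loss = ag.cross_entropy_with_logits(logits, y[idx], weights=w)
            state.zero_grad()
            loss.backward()
            lr = lr_at_step(step, train_cfg, total_steps)
            for name, p in state.params.items():
                g = p.grad if p.grad is not None else 0.0
                velocity[name] = train_cfg.momentum * velocity[name] - lr * g
                p.data += velocity[name]
                if train_cfg.weight_decay > 0 and _is_decayed(name):
                    p.data -= lr * train_cfg.weight_decay * p.data
            step += 1
            epoch_losses.append(float(loss.data))
        proba = predict_proba(train, state)
        acc = float((proba.argmax(axis=1) == y).mean())
        history.append({"epoch": epoch, "loss": float(np.mean(epoch_losses)),
                        "train_acc": acc,
                        "lr": lr_at_step(step, train_cfg, total_steps)})
        logger.info("epoch %d/%d loss %.4f acc %.4f", epoch, train_cfg.epochs,
                    history[-1]["loss"], acc)
    return state, pd.DataFrame(history)
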