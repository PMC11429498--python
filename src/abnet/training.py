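"""Supervised training of the encoder + classifier on normal behavior.

Optimization is plain stochastic gradient descent with momentum and
weight decay, cross-entropy loss, and a step learning-rate schedule.
Defaults follow the published recipe: initial learning rate 0.1, batch
size 64, 100 epochs, with random per-clip scaling in [0.97, 1.03] and a
per-clip translation of up to ±5 pixels applied to training batches
only.  The momentum (0.9), weight decay (1e-4) and the ×0.1 decay at
epochs 40/80 are conventional choices; the schedule is configurable.

All randomness (batch order, augmentation draws, adjacency noise) flows
from the single ``seed`` in :class:`TrainConfig`, so a run is exactly
reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from ._autograd import softmax_cross_entropy
from .io import ClipDataset, SkeletonSequence
from .network import STGCN

__all__ = ["TrainConfig", "TrainHistory", "augment", "train", "topk_accuracy"]


@dataclass
class TrainConfig:
    learning_rate: float = 0.1
    batch_size: int = 64
    epochs: int = 100
    momentum: float = 0.9
    weight_decay: float = 1e-4
    lr_decay_epochs: tuple[int, ...] = (40, 80)
    lr_decay_factor: float = 0.1
    scale_range: tuple[float, float] = (0.97, 1.03)
    shift_range_px: tuple[float, float] = (-5.0, 5.0)
    augment_on: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if self.scale_range[0] > self.scale_range[1]:
            raise ValueError("scale_range must be well-ordered")
        if self.shift_range_px[0] > self.shift_range_px[1]:
            raise ValueError("shift_range_px must be well-ordered")


@dataclass
class TrainHistory:
    """Per-epoch training record."""

    loss: list[float] = field(default_factory=list)
    train_top1: list[float] = field(default_factory=list)
    eval_top1: list[float] = field(default_factory=list)
    eval_top5: list[float] = field(default_factory=list)
    seed: int = 0
    config: TrainConfig | None = None


def augment(
    clip: SkeletonSequence, cfg: TrainConfig, rng: np.random.Generator
) -> SkeletonSequence:
    """Random per-clip scaling and translation of the x/y channels.

    One scalar scale is drawn uniformly from ``scale_range`` and one
    (dx, dy) shift uniformly from ``shift_range_px``; the pixel shift is
    converted to normalized units via the clip's stored frame size (half
    the larger dimension), matching the coordinate normalization.  The
    conf channel is untouched.
    """
    out = clip.data.copy()
    scale = rng.uniform(*cfg.scale_range)
    dx = rng.uniform(*cfg.shift_range_px)
    dy = rng.uniform(*cfg.shift_range_px)
    if clip.normalized and clip.frame_size is not None:
        half = max(clip.frame_size) / 2.0
        dx, dy = dx / half, dy / half
    out[:, 0] = out[:, 0] * scale + dx
    out[:, 1] = out[:, 1] * scale + dy
    return replace(clip, data=out)


def _augment_batch(
    batch: np.ndarray,
    template: SkeletonSequence,
    cfg: TrainConfig,
    rng: np.random.Generator,
) -> np.ndarray:
    out = batch.copy()
    half = (
        max(template.frame_size) / 2.0
        if template.normalized and template.frame_size is not None
        else 1.0
    )
    for i in range(out.shape[0]):
        scale = rng.uniform(*cfg.scale_range)
        dx = rng.uniform(*cfg.shift_range_px) / half
        dy = rng.uniform(*cfg.shift_range_px) / half
        out[i, 0] = out[i, 0] * scale + dx
        out[i, 1] = out[i, 1] * scale + dy
    return out


def topk_accuracy(probs: np.ndarray, labels: np.ndarray, k: int = 1) -> float:
    """Fraction of samples whose true class is among the top-k predictions.

    Ties are broken by class index: among equal probabilities the lower
    class index is ranked first.
    """
    probs = np.asarray(probs, dtype=float)
    labels = np.asarray(labels)
    if probs.ndim != 2 or probs.shape[0] != labels.shape[0]:
        raise ValueError("probs must be (n_samples, n_classes) matching labels")
    if not (1 <= k <= probs.shape[1]):
        raise ValueError(f"k={k} out of range for {probs.shape[1]} classes")
    n, c = probs.shape
    # stable sort on (-prob, class index): lexsort's last key is primary
    hits = 0
    idx = np.arange(c)
    for i in range(n):
        order = np.lexsort((idx, -probs[i]))
        if labels[i] in order[:k]:
            hits += 1
    return hits / n if n else 0.0


class SGD:
    """Stochastic gradient descent with classical momentum + weight decay."""

    def __init__(self, params, lr: float, momentum: float, weight_decay: float):
        self.params = params
        self.lr = lr
        self.momentum = momentum
        self.weight_decay = weight_decay
        self.velocity = [np.zeros_like(p.value) for p in params]

    def step(self) -> None:
        for p, v in zip(self.params, self.velocity):
            if p.grad is None:
                continue
            g = p.grad + self.weight_decay * p.value
            v *= self.momentum
            v += g
            p.value = p.value - self.lr * v

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None


def train(
    model: STGCN,
    train_ds: ClipDataset,
    eval_ds: ClipDataset | None,
    cfg: TrainConfig,
    verbose: bool = False,
) -> TrainHistory:
    """Fit encoder + classifier on labeled clips with SGD + cross-entropy.

    Augmentation applies to training batches only; adjacency noise (when
    enabled) is resampled per batch.  Returns the per-epoch history; the
    model is left in eval mode.
    """
    if train_ds.labels is None:
        raise ValueError("training requires a labeled dataset")
    if len(train_ds) == 0:
        raise ValueError("training dataset is empty")
    if len(np.unique(train_ds.labels)) < 2:
        raise ValueError("training requires at least 2 classes")

    rng = np.random.default_rng(cfg.seed)
    X = train_ds.stack()
    y = np.asarray(train_ds.labels)
    template = train_ds.clips[0]
    opt = SGD(model.parameters(), cfg.learning_rate, cfg.momentum, cfg.weight_decay)
    history = TrainHistory(seed=cfg.seed, config=cfg)

    for epoch in range(cfg.epochs):
        if epoch in cfg.lr_decay_epochs:
            opt.lr *= cfg.lr_decay_factor
        model.train_mode()
        perm = rng.permutation(len(X))
        epoch_loss, epoch_hits, seen = 0.0, 0, 0
        for start in range(0, len(X), cfg.batch_size):
            idx = perm[start : start + cfg.batch_size]
            batch = X[idx]
            if cfg.augment_on:
                batch = _augment_batch(batch, template, cfg, rng)
            opt.zero_grad()
            logits = model.forward_logits(batch, rng=rng)
            loss, probs = softmax_cross_entropy(logits, y[idx])
            loss.backward()
            opt.step()
            epoch_loss += float(loss.value) * len(idx)
            epoch_hits += int((probs.argmax(axis=1) == y[idx]).sum())
            seen += len(idx)
        history.loss.append(epoch_loss / seen)
        history.train_top1.append(epoch_hits / seen)
        if eval_ds is not None and eval_ds.labels is not None and len(eval_ds):
            probs = model.predict_proba(eval_ds.stack())
            k5 = min(5, probs.shape[1])
            history.eval_top1.append(topk_accuracy(probs, eval_ds.labels, 1))
            history.eval_top5.append(topk_accuracy(probs, eval_ds.labels, k5))
        if verbose:
            msg = (
                f"epoch {epoch:3d}  loss {history.loss[-1]:.4f}  "
                f"train top-1 {history.train_top1[-1]:.3f}"
            )
            if history.eval_top1:
                msg += f"  eval top-1 {history.eval_top1[-1]:.3f}"
            print(msg)
    model.eval_mode()
    return history
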