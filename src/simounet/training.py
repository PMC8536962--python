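"""Hybrid loss, deep-supervision objective, fold planning and training.

The per-image loss combines a (foreground-weighted) cross-entropy term
with a soft Dice coefficient,

    L = -(1/B) sum_b [ mean_r( 0.5 * y_r * ln(p_r) ) + (2*sum(y*p) + eps) / (sum(y) + sum(p) + eps) ],

so the minimum, -1, is reached exactly at a perfect prediction; the
training objective is the alpha-weighted sum of this loss over the five
heads (deep supervision on every prediction map).  Optimisation uses
RMSprop (lr 3e-4, decay 0.8, batch 32) with early stopping on the
validation loss and restoration of the best-validation weights.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import nn
from .architecture import HEAD_ORDER, SimouNet

logger = logging.getLogger(__name__)

__all__ = [
    "TrainingConfig",
    "FoldPlan",
    "hybrid_loss",
    "total_objective",
    "stratified_group_folds",
    "EarlyStopper",
    "train",
]

_EPS_CLIP = 1e-7


@dataclass
class TrainingConfig:
    learning_rate: float = 3e-4
    decay_factor_rho: float = 0.8
    batch_size: int = 32
    max_epochs: int = 1000
    early_stop_patience: int = 100
    alpha_weights: tuple = (1.0, 1.0, 1.0, 1.0, 1.0)
    smooth_eps: float = 1e-6
    seed: int = 0
    augmentation: bool = True

    def validate(self):
        if self.learning_rate <= 0 or self.decay_factor_rho <= 0:
            raise ValueError("learning_rate and decay_factor_rho must be > 0")
        if self.batch_size < 1 or self.max_epochs < 1:
            raise ValueError("batch_size and max_epochs must be >= 1")
        if len(self.alpha_weights) != 5:
            raise ValueError("alpha_weights must have length 5")
        if any(a < 0 for a in self.alpha_weights) or not any(
            a > 0 for a in self.alpha_weights
        ):
            raise ValueError("alpha_weights must be non-negative with at least one > 0")
        if not self.early_stop_patience < self.max_epochs:
            raise ValueError("early_stop_patience must be < max_epochs")
        return self


def _loss_tensor(pred, truth, smooth_eps):
    """Loss on tensors; pred/truth shaped (B, ...). The clip to
    [1e-7, 1-1e-7] applies inside the log only, so the Dice term keeps
    exact zero sums for empty predictions."""
    b = pred.shape[0]
    p = pred.reshape(b, -1)
    y = nn.as_tensor(truth).reshape(b, -1)
    bce = nn.tmean(y * nn.log(nn.clip(p, _EPS_CLIP, 1.0 - _EPS_CLIP)) * 0.5, axis=1)
    inter = nn.tsum(y * p, axis=1)
    sums = nn.tsum(y, axis=1) + nn.tsum(p, axis=1)
    dice = (inter * 2.0 + smooth_eps) / (sums + smooth_eps)
    return nn.tmean(bce + dice) * -1.0


def hybrid_loss(pred, truth, smooth_eps: float = 1e-6):
    """Combined cross-entropy + soft-Dice loss, averaged over the batch.

    Accepts numpy arrays (returns a float) or autodiff tensors (returns
    a tensor).  2D inputs are treated as a batch of one image.
    """
    if isinstance(pred, nn.Tensor):
        return _loss_tensor(pred, truth, smooth_eps)
    pred = np.asarray(pred, dtype=np.float32)
    truth = np.asarray(truth)
    if pred.shape != truth.shape:
        raise ValueError(f"pred shape {pred.shape} != truth shape {truth.shape}")
    if not np.all(np.isin(np.unique(truth), [0, 1])):
        raise ValueError("truth must be binary")
    if pred.ndim == 2:
        pred, truth = pred[None], truth[None]
    return float(_loss_tensor(nn.as_tensor(pred), truth.astype(np.float32), smooth_eps).item())


def total_objective(predictions, truth, alpha_weights, smooth_eps: float = 1e-6):
    """Alpha-weighted sum of the hybrid loss over the five heads.

    ``predictions`` is a dict head name -> map batch (or a
    PredictionSet); head order is ``HEAD_ORDER``, matching
    ``alpha_weights``.
    """
    if len(alpha_weights) != 5:
        raise ValueError("alpha_weights must have length 5")
    total = None
    for alpha, head in zip(alpha_weights, HEAD_ORDER):
        term = hybrid_loss(predictions[head], truth, smooth_eps)
        term = term * float(alpha)
        total = term if total is None else total + term
    return total


# -- fold planning -------------------------------------------------------


@dataclass
class FoldPlan:
    k: int
    assignments: dict = field(default_factory=dict)  # subject_id -> fold
    strata: dict = field(default_factory=dict)       # subject_id -> stratum

    def fold_subjects(self, fold: int):
        return sorted(s for s, f in self.assignments.items() if f == fold)

    def split(self, fold: int):
        """(train_ids, test_ids) for one fold used as the held-out set."""
        test = self.fold_subjects(fold)
        train = sorted(s for s, f in self.assignments.items() if f != fold)
        return train, test


def stratified_group_folds(manifest: pd.DataFrame, k: int, seed: int,
                           stratum_col: str = "stratum") -> FoldPlan:
    """Assign whole subjects to k folds, spreading each stratum as
    evenly as possible (within-stratum fold counts differ by <= 1).

    Slices of one subject never land in different folds because
    assignment is by subject.  Deterministic in ``seed``.
    """
    subjects = list(manifest["subject_id"])
    if len(set(subjects)) != len(subjects):
        raise ValueError("manifest contains duplicate subject_ids")
    if k > len(subjects):
        raise ValueError(f"k={k} exceeds number of subjects ({len(subjects)})")
    strata_series = (
        manifest[stratum_col] if stratum_col in manifest else pd.Series(["all"] * len(subjects))
    )
    rng = np.random.default_rng(int(seed))
    plan = FoldPlan(k=k)
    counts = np.zeros(k, dtype=int)
    by_stratum: dict = {}
    for sid, st in zip(subjects, strata_series):
        by_stratum.setdefault(st, []).append(sid)
        plan.strata[sid] = st
    for st in sorted(by_stratum, key=str):
        members = sorted(by_stratum[st])
        rng.shuffle(members)
        # deal round-robin starting from the currently smallest folds
        order = np.argsort(counts, kind="stable")
        for i, sid in enumerate(members):
            fold = int(order[i % k])
            plan.assignments[sid] = fold
            counts[fold] += 1
    return plan


# -- training loop -------------------------------------------------------


class EarlyStopper:
    """Stop when the monitored loss has not improved for `patience`
    epochs; remembers the best epoch (1-based)."""

    def __init__(self, patience: int):
        self.patience = patience
        self.best = np.inf
        self.best_epoch = 0
        self.epoch = 0

    def update(self, loss: float) -> bool:
        """Record one epoch's loss; return True if training should stop."""
        self.epoch += 1
        if loss < self.best:
            self.best = loss
            self.best_epoch = self.epoch
        return (self.epoch - self.best_epoch) >= self.patience


def _epoch_samples(images, masks, cfg, rng):
    """With augmentation on, each epoch sees every original plus one
    freshly augmented copy of it."""
    if not cfg.augmentation:
        return images, masks
    from .phantom import augment

    aug_i = np.empty_like(images)
    aug_m = np.empty_like(masks)
    for i in range(images.shape[0]):
        ai, am = augment(images[i], masks[i], rng)
        aug_i[i], aug_m[i] = ai, am.astype(masks.dtype)
    return np.concatenate([images, aug_i]), np.concatenate([masks, aug_m])


def _eval_loss_and_metrics(model: SimouNet, images, masks, cfg):
    from .architecture import predict
    from .fusion import binarize, fuse
    from .metrics import confusion_counts, overlap_metrics

    preds = predict(model, images, batch_size=cfg.batch_size)
    loss = total_objective(
        {h: preds[h] for h in HEAD_ORDER}, masks.astype(np.float32),
        cfg.alpha_weights, cfg.smooth_eps,
    )
    fused = fuse(preds, "mean").values
    tp, fp, fn, _ = confusion_counts(binarize(fused, 0.5), masks)
    j, d, _sen = overlap_metrics(tp, fp, fn)
    return float(loss), (d if d is not None else np.nan), (j if j is not None else np.nan)


def train(model: SimouNet, train_samples, val_samples, config: TrainingConfig):
    """Optimise the deep-supervision objective; returns (history, info).

    ``train_samples``/``val_samples`` are (images, masks) pairs of
    (N, H, W) arrays; images in intensity units, masks binary.  The
    best-validation weights are restored before returning.  History is
    a DataFrame with per-epoch train/val loss and validation Dice /
    Jaccard of the mean-fused prediction.
    """
    config.validate()
    tr_images, tr_masks = (np.asarray(a) for a in train_samples)
    va_images, va_masks = (np.asarray(a) for a in val_samples)
    if tr_images.shape[0] == 0 or va_images.shape[0] == 0:
        raise ValueError("train and validation sets must be non-empty")
    rng = np.random.default_rng(int(config.seed))
    model.reseed_dropout(config.seed)
    opt = nn.RMSprop(model.parameters(), lr=config.learning_rate,
                     rho=config.decay_factor_rho)
    stopper = EarlyStopper(config.early_stop_patience)
    best_state = model.state_dict()
    rows = []
    for epoch in range(1, config.max_epochs + 1):
        ep_images, ep_masks = _epoch_samples(tr_images, tr_masks, config, rng)
        order = rng.permutation(ep_images.shape[0])
        model.train()
        batch_losses = []
        for lo in range(0, len(order), config.batch_size):
            idx = order[lo:lo + config.batch_size]
            x = nn.Tensor(ep_images[idx][..., None])
            y = ep_masks[idx].astype(np.float32)
            out = model.forward(x)
            loss = total_objective(out, y, config.alpha_weights, config.smooth_eps)
            if not np.isfinite(loss.item()):
                raise RuntimeError(
                    f"non-finite training loss at epoch {epoch}, batch {lo // config.batch_size}"
                )
            opt.zero_grad()
            loss.backward()
            opt.step()
            batch_losses.append(loss.item())
        train_loss = float(np.mean(batch_losses))
        val_loss, val_dice, val_jaccard = _eval_loss_and_metrics(
            model, va_images, va_masks, config
        )
        rows.append(
            {"epoch": epoch, "train_loss": train_loss, "val_loss": val_loss,
             "val_dice": val_dice, "val_jaccard": val_jaccard}
        )
        logger.info(
            "epoch %d: train_loss=%.4f val_loss=%.4f val_dice=%.4f val_jaccard=%.4f",
            epoch, train_loss, val_loss, val_dice, val_jaccard,
        )
        improved = val_loss < stopper.best
        stop = stopper.update(val_loss)
        if improved:
            best_state = model.state_dict()
        if stop:
            logger.info("early stop at epoch %d (best epoch %d)", epoch, stopper.best_epoch)
            break
    model.load_state_dict(best_state)
    history = pd.DataFrame(rows)
    info = {"best_epoch": stopper.best_epoch, "best_val_loss": stopper.best,
            "stopped_epoch": stopper.epoch}
    return history, info
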