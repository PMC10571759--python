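"""Training loop: pixel-averaged binary cross-entropy, Adam with
decoupled weight decay, per-epoch validation Dice, best-checkpoint
selection, and a serialisable history."""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import nn
from .metrics import dice
from .nn import functional as F

logger = logging.getLogger(__name__)

__all__ = ["TrainConfig", "FitResult", "bce_loss", "fit", "evaluate_dice"]


@dataclass
class TrainConfig:
    """Optimisation settings.

    Defaults follow the Adam configuration the model was designed
    around: learning rate 1e-3, weight decay 1e-6 (decoupled), batch
    size 32.  ``epochs`` counts passes over the training crops.
    """

    learning_rate: float = 1e-3
    weight_decay: float = 1e-6
    batch_size: int = 32
    epochs: int = 100
    seed: int = 0
    selection: str = "val_dice"   # checkpoint rule: best validation Dice
    threshold: float = 0.5        # binarisation for the Dice monitor

    def __post_init__(self):
        if self.learning_rate < 0 or self.weight_decay < 0:
            raise ValueError("rates must be nonnegative")
        if self.batch_size <= 0 or self.epochs <= 0:
            raise ValueError("batch size and epochs must be positive")
        if self.selection not in ("val_dice", "val_loss", "last"):
            raise ValueError(f"unknown selection rule {self.selection!r}")

    def to_dict(self):
        return dict(vars(self))


def bce_loss(pred_prob, gt, eps: float = 1e-7) -> float:
    """Mean per-pixel binary cross-entropy between a probability map and
    a binary target, with probabilities clipped to [eps, 1-eps]."""
    p = np.asarray(pred_prob, dtype=np.float64)
    y = np.asarray(gt, dtype=np.float64)
    if p.shape != y.shape:
        raise ValueError(f"shape mismatch: {p.shape} vs {y.shape}")
    pc = np.clip(p, eps, 1.0 - eps)
    return float(np.mean(-y * np.log(pc) - (1.0 - y) * np.log(1.0 - pc)))


@dataclass
class FitResult:
    history: pd.DataFrame
    best_epoch: int
    best_val_dice: float

    def save(self, out_dir):
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        self.history.to_csv(out_dir / "history.csv", index=False)


def evaluate_dice(model, x, y, threshold=0.5, batch_size=8) -> float:
    """Mean per-crop Dice of thresholded predictions."""
    probs = model.predict(x, batch_size=batch_size)
    scores = [dice(probs[i, ..., 0] >= threshold, y[i, ..., 0] > 0.5)
              for i in range(len(x))]
    return float(np.mean(scores))


def fit(model, train_crops, val_crops, config: TrainConfig,
        out_dir=None, train_patients=None, val_patients=None,
        log_every=0) -> FitResult:
    """Seeded mini-batch training with best-validation-Dice selection.

    ``train_crops`` / ``val_crops`` are (X, Y) pairs of float32 arrays —
    images in [0, 1] with shape (n, s, s, 3), masks (n, s, s, 1).  When
    patient lists are supplied, train/validation provenance is asserted
    disjoint.  The model is left holding the selected best weights.
    """
    x_tr, y_tr = train_crops
    x_va, y_va = val_crops
    if len(x_tr) == 0 or len(x_va) == 0:
        raise ValueError("training and validation crops must be nonempty")
    if train_patients is not None and val_patients is not None:
        common = set(train_patients) & set(val_patients)
        if common:
            raise ValueError(f"patient leakage between train and val: {common}")

    rng = np.random.default_rng(config.seed)
    opt = nn.AdamW(model.parameters(), lr=config.learning_rate,
                   weight_decay=config.weight_decay)
    rows = []
    best = (-np.inf, None, -1)  # (score, state, epoch)
    for epoch in range(1, config.epochs + 1):
        order = rng.permutation(len(x_tr))
        losses = []
        for start in range(0, len(order), config.batch_size):
            idx = order[start:start + config.batch_size]
            out = model.forward(x_tr[idx], training=True)
            loss = F.bce_mean(out, y_tr[idx])
            if not np.isfinite(loss.data):
                raise FloatingPointError(
                    f"non-finite training loss at epoch {epoch}")
            opt.zero_grad()
            loss.backward()
            opt.step()
            losses.append(float(loss.data))
        val_prob = model.predict(x_va, batch_size=config.batch_size)
        val_loss = bce_loss(val_prob, y_va)
        val_dice = float(np.mean([
            dice(val_prob[i, ..., 0] >= config.threshold, y_va[i, ..., 0] > 0.5)
            for i in range(len(x_va))]))
        rows.append({"epoch": epoch, "train_loss": float(np.mean(losses)),
                     "val_loss": val_loss, "val_dice": val_dice})
        if log_every and epoch % log_every == 0:
            logger.info("epoch %d: train %.4f val %.4f dice %.4f",
                        epoch, rows[-1]["train_loss"], val_loss, val_dice)
        score = {"val_dice": val_dice, "val_loss": -val_loss,
                 "last": epoch}[config.selection]
        if score > best[0]:
            best = (score, {k: v.copy() for k, v in model.state_dict().items()},
                    epoch)
    if best[1] is not None:
        model.load_state_dict(best[1])
    history = pd.DataFrame(rows)
    result = FitResult(history=history, best_epoch=best[2],
                       best_val_dice=float(history["val_dice"].max()))
    if out_dir is not None:
        result.save(out_dir)
        model.save(Path(out_dir) / "weights.npz")
    return result
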