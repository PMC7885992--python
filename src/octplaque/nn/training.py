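"""Shared training loop: Adam, stepped LR schedule, early stopping.

Both networks are optimized the same way: Adam with initial learning
rate 0.001, dropped by a factor of 0.2 every 5 epochs, for at most 50
epochs or until the validation loss has not improved for 5 consecutive
epochs, whichever comes first.  The best-validation weights are
restored at the end.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable

import numpy as np

from .layers import Sequential
from .optim import Adam


@dataclass
class TrainConfig:
    lr: float = 0.001
    drop_factor: float = 0.2
    drop_period: int = 5
    max_epochs: int = 50
    patience: int = 5
    batch_size: int = 8
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.lr, self.drop_factor) <= 0 or min(self.drop_period, self.max_epochs,
                                                      self.patience, self.batch_size) <= 0:
            raise ValueError("all TrainConfig fields must be positive")
        if self.patience > self.max_epochs:
            raise ValueError("patience must not exceed max_epochs")


def lr_at_epoch(cfg: TrainConfig, epoch: int) -> float:
    """Learning rate for a 1-based epoch under the stepped schedule."""
    return cfg.lr * cfg.drop_factor ** ((epoch - 1) // cfg.drop_period)


def _batches(n: int, batch_size: int, perm: np.ndarray):
    for i in range(0, n, batch_size):
        yield perm[i : i + batch_size]


def evaluate_loss(model: Sequential, loss_fn, X, y, batch_size: int = 8) -> float:
    total, count = 0.0, 0
    for i in range(0, len(X), batch_size):
        logits = model.forward(X[i : i + batch_size], training=False)
        loss, _ = loss_fn(logits, y[i : i + batch_size])
        total += loss * len(X[i : i + batch_size])
        count += len(X[i : i + batch_size])
    return total / max(count, 1)


def fit(
    model: Sequential,
    loss_fn: Callable,
    X: np.ndarray,
    y: np.ndarray,
    X_val: np.ndarray,
    y_val: np.ndarray,
    cfg: TrainConfig,
    val_evaluator: Callable[[Sequential, int], float] | None = None,
) -> dict:
    """Train in place; return a history dict.

    ``loss_fn(logits, targets) -> (loss, dloss_dlogits)``.
    ``val_evaluator`` overrides validation-loss computation (used by
    tests to exercise the early-stopping contract deterministically).
    """
    rng = np.random.default_rng(cfg.seed)
    opt = Adam(model.params())
    history: dict = {"train_loss": [], "val_loss": [], "lr": [], "stopped_epoch": None}
    best_val, best_state, bad = np.inf, model.get_state(), 0
    for epoch in range(1, cfg.max_epochs + 1):
        lr = lr_at_epoch(cfg, epoch)
        perm = rng.permutation(len(X))
        ep_loss, seen = 0.0, 0
        for idx in _batches(len(X), cfg.batch_size, perm):
            model.zero_grad()
            logits = model.forward(X[idx], training=True)
            loss, dlogits = loss_fn(logits, y[idx])
            model.backward(dlogits)
            opt.step(lr)
            ep_loss += loss * len(idx)
            seen += len(idx)
        if val_evaluator is not None:
            vloss = val_evaluator(model, epoch)
        else:
            vloss = evaluate_loss(model, loss_fn, X_val, y_val, cfg.batch_size)
        history["train_loss"].append(ep_loss / seen)
        history["val_loss"].append(vloss)
        history["lr"].append(lr)
        if vloss < best_val - 1e-12:
            best_val, best_state, bad = vloss, model.get_state(), 0
        else:
            bad += 1
            if bad >= cfg.patience:
                history["stopped_epoch"] = epoch
                break
    model.set_state(best_state)
    return history
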