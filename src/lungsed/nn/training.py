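"""Training loop: Adam, per-frame BCE, plateau LR decay, early stopping.

The schedule mirrors the benchmark protocol: Adam with initial learning
rate 1e-4; when the validation loss has not decreased for
``lr_patience_epochs`` (10) consecutive epochs the learning rate is
multiplied by ``lr_decay_factor`` (0.2); training stops after
``early_stop_epochs`` (50) consecutive epochs without improvement, and
the best-validation-loss weights are restored.  "Improvement" means a
strictly lower validation loss (tolerance 0); the two patience counters
run independently.

The loss is per-frame binary cross-entropy computed on logits (the
model's final dense layer is linear; the sigmoid lives inside the loss
for numerical stability and inside ``SequenceModel.scores`` for
inference).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .layers import DTYPE, SequenceModel, _sigmoid


@dataclass
class TrainConfig:
    """Optimization hyper-parameters; defaults are the benchmark protocol."""

    initial_lr: float = 1e-4
    lr_decay_factor: float = 0.2
    lr_patience_epochs: int = 10
    early_stop_epochs: int = 50
    batch_size: int = 32
    max_epochs: int = 500
    seed: int = 0

    def validate(self) -> None:
        for name in ("initial_lr", "lr_decay_factor", "lr_patience_epochs",
                     "early_stop_epochs", "batch_size", "max_epochs"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


class Adam:
    """Adam on a dict of parameter arrays (updated in place)."""

    def __init__(self, params: dict[str, np.ndarray], lr: float,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.params = params
        self.lr = lr
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.m = {k: np.zeros_like(v) for k, v in params.items()}
        self.v = {k: np.zeros_like(v) for k, v in params.items()}
        self.t = 0

    def step(self, grads: dict[str, np.ndarray]) -> None:
        self.t += 1
        b1t = 1.0 - self.beta1**self.t
        b2t = 1.0 - self.beta2**self.t
        for k, p in self.params.items():
            g = grads[k]
            self.m[k] = self.beta1 * self.m[k] + (1 - self.beta1) * g
            self.v[k] = self.beta2 * self.v[k] + (1 - self.beta2) * g * g
            mhat = self.m[k] / b1t
            vhat = self.v[k] / b2t
            p -= (self.lr * mhat / (np.sqrt(vhat) + self.eps)).astype(p.dtype)


@dataclass
class TrainingHistory:
    """Per-epoch record of losses and learning rate."""

    epochs: list[int] = field(default_factory=list)
    train_loss: list[float] = field(default_factory=list)
    val_loss: list[float] = field(default_factory=list)
    lr: list[float] = field(default_factory=list)
    stopped_epoch: int | None = None
    best_epoch: int | None = None

    def append(self, epoch: int, train: float, val: float, lr: float) -> None:
        self.epochs.append(epoch)
        self.train_loss.append(train)
        self.val_loss.append(val)
        self.lr.append(lr)

    def to_rows(self) -> list[dict]:
        return [
            {"epoch": e, "train_loss": t, "val_loss": v, "lr": l}
            for e, t, v, l in zip(self.epochs, self.train_loss,
                                  self.val_loss, self.lr)
        ]


def bce_with_logits(logits: np.ndarray, targets: np.ndarray) -> float:
    """Mean binary cross-entropy, numerically stable on logits."""
    z = np.asarray(logits, dtype=np.float64)
    y = np.asarray(targets, dtype=np.float64)
    loss = np.maximum(z, 0) - z * y + np.log1p(np.exp(-np.abs(z)))
    return float(loss.mean())


def evaluate_loss(model: SequenceModel, X: np.ndarray, Y: np.ndarray,
                  batch_size: int = 32) -> float:
    total, count = 0.0, 0
    for a in range(0, len(X), batch_size):
        xb, yb = X[a:a + batch_size], Y[a:a + batch_size]
        logits = model.forward(xb)
        total += bce_with_logits(logits, yb) * yb.size
        count += yb.size
    return total / count


def fit(model: SequenceModel, X_train: np.ndarray, Y_train: np.ndarray,
        X_val: np.ndarray, Y_val: np.ndarray,
        config: TrainConfig | None = None,
        verbose: bool = False) -> TrainingHistory:
    """Train in place; returns the history.  Deterministic under the seed."""
    config = config or TrainConfig()
    config.validate()
    if len(X_train) == 0:
        raise ValueError("empty training set")
    X_train = np.asarray(X_train, dtype=DTYPE)
    Y_train = np.asarray(Y_train, dtype=DTYPE)
    X_val = np.asarray(X_val, dtype=DTYPE)
    Y_val = np.asarray(Y_val, dtype=DTYPE)

    rng = np.random.default_rng(config.seed)
    optimizer = Adam(model.params(), lr=config.initial_lr)
    history = TrainingHistory()

    best_val = np.inf
    best_weights = model.get_weights()
    best_epoch = 0
    lr_wait = 0
    stop_wait = 0

    for epoch in range(1, config.max_epochs + 1):
        order = rng.permutation(len(X_train))
        epoch_loss, n_frames = 0.0, 0
        for a in range(0, len(order), config.batch_size):
            idx = order[a:a + config.batch_size]
            xb, yb = X_train[idx], Y_train[idx]
            logits = model.forward(xb)
            epoch_loss += bce_with_logits(logits, yb) * yb.size
            n_frames += yb.size
            dlogits = (_sigmoid(logits) - yb) / yb.size
            model.backward(dlogits)
            optimizer.step(model.grads())

        train_loss = epoch_loss / n_frames
        val_loss = evaluate_loss(model, X_val, Y_val, config.batch_size)
        history.append(epoch, train_loss, val_loss, optimizer.lr)
        if verbose:
            print(f"epoch {epoch:4d}  train {train_loss:.4f}  "
                  f"val {val_loss:.4f}  lr {optimizer.lr:.2e}")

        if val_loss < best_val:
            best_val = val_loss
            best_weights = model.get_weights()
            best_epoch = epoch
            lr_wait = 0
            stop_wait = 0
        else:
            lr_wait += 1
            stop_wait += 1
            if lr_wait >= config.lr_patience_epochs:
                optimizer.lr *= config.lr_decay_factor
                lr_wait = 0
            if stop_wait >= config.early_stop_epochs:
                history.stopped_epoch = epoch
                break

    model.set_weights(best_weights)
    history.best_epoch = best_epoch
    return history
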