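"""Dataset splitting and gradient-based model fitting.

The dataset is randomly partitioned into a training set (default 70%) and
a held-out test set (30%); the test set is never touched during fitting or
hyperparameter choice.  Parameters are optimized by minimizing the
mean-squared error L = (1/N) sum_n (y_n - y^_n)^2 on normalized sequences
with Adam, one record per gradient contribution, gradients averaged over
each mini-batch.  Runs are deterministic given the config seed (shuffling)
and the model seed (initialization and dropout).
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Callable, Sequence

import numpy as np

from .cohort import PairedRecord
from .errors import TrainingDivergedError, ValidationError
from .model.layers import Param
from .model.network import TCNAttention
from .preprocessing import NormalizationScheme

__all__ = ["TrainConfig", "FitResult", "Adam", "split_dataset", "mse_loss",
           "prepare_pairs", "fit"]


@dataclass(frozen=True)
class TrainConfig:
    train_fraction: float = 0.70
    epochs: int = 30
    batch_size: int = 16
    learning_rate: float = 1e-3
    seed: int = 0
    optimizer: str = "adam"
    early_stop_patience: int | None = None

    def __post_init__(self) -> None:
        if not 0.0 < self.train_fraction < 1.0:
            raise ValidationError("train_fraction must be in (0, 1)")
        if not self.learning_rate > 0:
            raise ValidationError("learning_rate must be > 0")
        if self.epochs < 1 or self.batch_size < 1:
            raise ValidationError("epochs and batch_size must be >= 1")
        if self.optimizer != "adam":
            raise ValidationError(f"unknown optimizer {self.optimizer!r}")


@dataclass
class FitResult:
    loss_history: list[float]
    epochs_run: int


class Adam:
    """Adaptive-moment gradient descent with bias correction."""

    def __init__(self, params: Sequence[Param], lr: float = 1e-3,
                 betas: tuple[float, float] = (0.9, 0.999), eps: float = 1e-8):
        self.params = list(params)
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self._m = [np.zeros_like(p.value) for p in self.params]
        self._v = [np.zeros_like(p.value) for p in self.params]

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad[...] = 0.0

    def step(self) -> None:
        self.t += 1
        c1 = 1.0 - self.b1 ** self.t
        c2 = 1.0 - self.b2 ** self.t
        for p, m, v in zip(self.params, self._m, self._v):
            m *= self.b1
            m += (1.0 - self.b1) * p.grad
            v *= self.b2
            v += (1.0 - self.b2) * p.grad ** 2
            p.value -= self.lr * (m / c1) / (np.sqrt(v / c2) + self.eps)


def split_dataset(records: Sequence, train_fraction: float = 0.70,
                  seed: int = 0) -> tuple[list, list]:
    """Random disjoint, exhaustive train/test partition by seed.

    Train size is round(n * fraction).  The returned test set is reserved
    for final evaluation and must not inform any tuning decision.
    """
    records = list(records)
    n = len(records)
    if n < 2:
        raise ValidationError("need at least 2 records to split")
    if not 0.0 < train_fraction < 1.0:
        raise ValidationError("train_fraction must be in (0, 1)")
    order = np.random.default_rng(seed).permutation(n)
    n_train = int(round(n * train_fraction))
    train = [records[i] for i in order[:n_train]]
    test = [records[i] for i in order[n_train:]]
    return train, test


def mse_loss(y, y_hat) -> float:
    """Mean squared error L = (1/N) sum (y_n - y^_n)^2."""
    y = np.asarray(y, dtype=np.float64)
    y_hat = np.asarray(y_hat, dtype=np.float64)
    if y.shape != y_hat.shape or y.ndim != 1 or y.size < 1:
        raise ValidationError("sequences must be 1-D with equal length >= 1")
    return float(np.mean((y - y_hat) ** 2))


def prepare_pairs(records: Sequence[PairedRecord],
                  scheme: NormalizationScheme | None = None
                  ) -> list[tuple[np.ndarray, np.ndarray]]:
    """Normalize whole records into (input, target) training pairs."""
    scheme = scheme or NormalizationScheme()
    return [(scheme.apply(r.radial.values), scheme.apply(r.aortic.values))
            for r in records]


def fit(model: TCNAttention, pairs: Sequence[tuple[np.ndarray, np.ndarray]],
        config: TrainConfig | None = None,
        callback: Callable[[int, float], None] | None = None) -> FitResult:
    """Minimize the MSE loss over whole-record (x, y) pairs.

    Records are shuffled each epoch; each mini-batch averages per-record
    gradients before one Adam step.  The per-epoch mean training loss is
    recorded; a non-finite loss aborts with a diagnostic.
    """
    config = config or TrainConfig()
    pairs = list(pairs)
    if not pairs:
        raise ValidationError("training set is empty")
    for x, y in pairs:
        if len(x) != len(y):
            raise ValidationError("each pair must have equal input/target length")
    rng = np.random.default_rng(config.seed)
    opt = Adam(model.params(), lr=config.learning_rate)
    history: list[float] = []
    best = np.inf
    stale = 0
    for epoch in range(config.epochs):
        order = rng.permutation(len(pairs))
        losses = []
        for start in range(0, len(order), config.batch_size):
            batch = order[start:start + config.batch_size]
            opt.zero_grad()
            for i in batch:
                x, y = pairs[i]
                y_hat = model.forward(x, training=True)
                losses.append(mse_loss(y, y_hat))
                model.backward(2.0 * (y_hat - y) / (len(y) * len(batch)))
            opt.step()
        epoch_loss = float(np.mean(losses))
        if not np.isfinite(epoch_loss):
            raise TrainingDivergedError(
                f"non-finite training loss at epoch {epoch}: {epoch_loss} "
                f"(lr={config.learning_rate})"
            )
        history.append(epoch_loss)
        if callback is not None:
            callback(epoch, epoch_loss)
        if config.early_stop_patience is not None:
            # relative improvement threshold: plateau = < 1e-6 relative gain
            if epoch_loss < best * (1.0 - 1e-6):
                best, stale = epoch_loss, 0
            else:
                stale += 1
                if stale >= config.early_stop_patience:
                    break
    return FitResult(loss_history=history, epochs_run=len(history))
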