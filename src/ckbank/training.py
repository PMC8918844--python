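"""Training recipe: AdamW, step learning-rate schedule, frozen encoder.

The recipe mirrors a standard transfer-learning regime for medical image
classification: the encoder is frozen and only the projection head and
the knowledge banks receive updates.  Defaults are learning rate 5e-4,
decoupled weight decay 0.01, a step scheduler with step size 2 epochs
and decay factor 0.6, batch size 64, 20 epochs, and 64 units per bank.

The loop is single-process NumPy, so identical (data, config, seed)
always yields bit-identical parameters.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields, replace

import numpy as np
import pandas as pd

from .bank import ClassKnowledgeBank
from .errors import ConfigurationError, DataError, LabelError
from .heads import BankHead
from .network import Module, Parameter, ProjectionHead

__all__ = ["TrainingConfig", "TrainingHistory", "AdamW", "lr_at_epoch", "train"]


@dataclass(frozen=True)
class TrainingConfig:
    """Optimizer, scheduler and bank hyperparameters.

    ``dim`` is the unit / representation dimension D; it defaults to 512
    (matching the width of the three-layer comparison classifiers) but is
    routinely set to 8-32 in tests and desk-scale runs.
    """

    learning_rate: float = 5e-4
    weight_decay: float = 0.01
    scheduler_step: int = 2
    scheduler_gamma: float = 0.6
    batch_size: int = 64
    epochs: int = 20
    units_per_class: int = 64
    dim: int = 512
    seed: int = 0
    freeze_encoder: bool = True

    def __post_init__(self):
        if self.learning_rate < 0 or self.weight_decay < 0:
            raise ConfigurationError("rates must be nonnegative")
        if self.scheduler_gamma <= 0 or self.scheduler_step < 1:
            raise ConfigurationError("invalid scheduler settings")
        if min(self.epochs, self.batch_size, self.units_per_class, self.dim) < 1:
            raise ConfigurationError("epochs, batch_size, M and D must be >= 1")

    def replace(self, **kw) -> "TrainingConfig":
        return replace(self, **kw)

    def to_dict(self) -> dict:
        return {f.name: getattr(self, f.name) for f in fields(self)}


def lr_at_epoch(config: TrainingConfig, epoch: int) -> float:
    """Step schedule: ``lr0 * gamma ** floor(epoch / step)``."""
    if epoch < 0:
        raise ConfigurationError("epoch must be >= 0")
    return config.learning_rate * config.scheduler_gamma ** (epoch // config.scheduler_step)


@dataclass
class TrainingHistory:
    """One record per completed epoch."""

    frame: pd.DataFrame = field(
        default_factory=lambda: pd.DataFrame(
            columns=["epoch", "loss_total", "loss_con", "loss_cel",
                     "train_accuracy", "learning_rate"]
        )
    )

    def append(self, **row) -> None:
        self.frame.loc[len(self.frame)] = row

    def to_csv(self, path) -> None:
        self.frame.to_csv(path, index=False)


class AdamW(Module):
    """Adam with decoupled weight decay.

    Weight decay only touches parameters flagged ``decay=True`` (weight
    matrices and bank units; biases and normalization scale/shift are
    exempt) and is applied directly to the parameter, not to the
    gradient.
    """

    def __init__(self, params: list[Parameter], weight_decay: float = 0.01,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.params = params
        self.weight_decay = weight_decay
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.m = [np.zeros_like(p.value) for p in params]
        self.v = [np.zeros_like(p.value) for p in params]
        self.t = 0

    def step(self, lr: float) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for p, m, v in zip(self.params, self.m, self.v):
            m *= b1
            m += (1 - b1) * p.grad
            v *= b2
            v += (1 - b2) * p.grad**2
            mhat = m / (1 - b1**self.t)
            vhat = v / (1 - b2**self.t)
            if p.decay:
                p.value -= lr * self.weight_decay * p.value
            p.value -= lr * mhat / (np.sqrt(vhat) + self.eps)

    def zero_grad(self) -> None:
        for p in self.params:
            p.zero_grad()


def _encode_all(encoder: Module, X: np.ndarray, chunk: int = 256) -> np.ndarray:
    outs = [encoder.forward(X[i : i + chunk]) for i in range(0, len(X), chunk)]
    return np.concatenate(outs, axis=0)


def train_head(head, encoder: Module, projection: ProjectionHead,
               X: np.ndarray, y: np.ndarray, config: TrainingConfig) -> TrainingHistory:
    """Shared loop behind :func:`train` and the head comparison.

    When the encoder is frozen (the default) its outputs are computed
    once and cached — the gradient never needs to flow through it.
    """
    X = np.asarray(X, dtype=np.float64)
    y = np.asarray(y)
    if len(X) == 0:
        raise DataError("empty training set")
    if len(X) != len(y):
        raise DataError(f"{len(X)} samples but {len(y)} labels")
    y = y.astype(np.int64)
    if np.any(y < 0) or np.any(y >= head.n_classes):
        raise LabelError(f"labels must lie in [0, {head.n_classes})")

    encoder_trainable = (
        not config.freeze_encoder
        and getattr(getattr(encoder, "spec", None), "trainable", False)
    )
    params = head.parameters() + projection.parameters()
    if encoder_trainable:
        params += encoder.parameters()
    opt = AdamW(params, weight_decay=config.weight_decay)

    cache = None if encoder_trainable else _encode_all(encoder, X)

    rng = np.random.default_rng(config.seed)
    n = len(X)
    history = TrainingHistory()
    for epoch in range(config.epochs):
        lr = lr_at_epoch(config, epoch)
        order = rng.permutation(n)
        sums = np.zeros(3)
        correct = 0
        for start in range(0, n, config.batch_size):
            idx = order[start : start + config.batch_size]
            r0 = cache[idx] if cache is not None else encoder.forward(X[idx])
            r = projection.forward(r0, train=True)
            loss, grad_R = head.loss_and_grads(r, y[idx])
            g0 = projection.backward(grad_R)
            if encoder_trainable:
                encoder.backward(g0)
            b = len(idx)
            sums += b * np.array([loss.total, loss.contrastive, loss.cross_entropy])
            correct += int(np.sum(np.argmax(np.atleast_2d(head.logits(r)), axis=1) == y[idx]))
            opt.step(lr)
            opt.zero_grad()
        history.append(
            epoch=epoch,
            loss_total=sums[0] / n,
            loss_con=sums[1] / n,
            loss_cel=sums[2] / n,
            train_accuracy=correct / n,
            learning_rate=lr,
        )
    return history


def train(bank: ClassKnowledgeBank, encoder: Module, projection: ProjectionHead,
          data: tuple[np.ndarray, np.ndarray], config: TrainingConfig):
    """Train the bank and projection head on labeled data.

    Parameters
    ----------
    data
        ``(X, y)``: inputs matching the encoder's expected shape, and
        integer labels below ``bank.n_classes``.

    Returns
    -------
    (trained_bank, projection, history)
        The projection head is updated in place and also returned.
    """
    X, y = data
    head = BankHead(bank)
    history = train_head(head, encoder, projection, X, y, config)
    return head.bank, projection, history
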