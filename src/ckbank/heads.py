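"""Classification heads: the knowledge-bank head and a linear baseline.

Both expose the same protocol — ``logits(R)``, ``loss_and_grads(R, y)``,
``parameters()`` — so the training loop and the imbalance comparison can
swap one for the other while everything upstream (encoder, projection,
data order) stays identical.
"""

from __future__ import annotations

import numpy as np

from . import bank as bank_mod
from .bank import ClassKnowledgeBank, LossValue, softmax_probabilities
from .errors import LabelError, ShapeError
from .network import Linear, Module, Parameter


class BankHead(Module):
    """Knowledge-bank head: logits are mean cosine similarities.

    Trains with the combined contrastive + cross-entropy objective.
    """

    kind = "ckb"

    def __init__(self, bank: ClassKnowledgeBank):
        self.units = Parameter(bank.units.copy(), decay=True, name="bank.units")
        self.init_seed = bank.seed
        self.n_classes = bank.n_classes

    def parameters(self):
        return [self.units]

    @property
    def bank(self) -> ClassKnowledgeBank:
        return ClassKnowledgeBank(units=self.units.value, seed=self.init_seed)

    def logits(self, R: np.ndarray) -> np.ndarray:
        return bank_mod.ckb_logits(self.bank, R)

    def loss_and_grads(self, R: np.ndarray, y: np.ndarray):
        """Batch-mean loss; accumulates the unit gradient, returns grad wrt R."""
        loss, grad_units, grad_R = bank_mod.loss_and_grads(self.bank, R, y)
        self.units.grad += grad_units
        return loss, grad_R


class LinearHead(Module):
    """Affine logits trained with cross-entropy only — the conventional head."""

    kind = "linear"

    def __init__(self, dim: int, n_classes: int, seed: int = 0):
        rng = np.random.default_rng(seed)
        self.linear = Linear(dim, n_classes, rng, "head")
        self.n_classes = n_classes
        self.dim = dim

    def parameters(self):
        return self.linear.parameters()

    def logits(self, R: np.ndarray) -> np.ndarray:
        R = np.asarray(R, dtype=np.float64)
        single = R.ndim == 1
        z = self.linear.forward(R[None, :] if single else R)
        return z[0] if single else z

    def loss_and_grads(self, R: np.ndarray, y: np.ndarray):
        R = np.asarray(R, dtype=np.float64)
        if R.ndim != 2 or R.shape[1] != self.dim:
            raise ShapeError(f"expected (B, {self.dim}); got {R.shape}")
        y = np.asarray(y, dtype=np.int64)
        if np.any(y < 0) or np.any(y >= self.n_classes):
            raise LabelError(f"label out of range for {self.n_classes} classes")
        B = len(R)
        z = self.linear.forward(R)
        p = softmax_probabilities(z)
        cel = float(np.mean(bank_mod.cross_entropy_loss(z, y)))
        gz = p.copy()
        gz[np.arange(B), y] -= 1.0
        gz /= B
        grad_R = self.linear.backward(gz)
        loss = LossValue(contrastive=0.0, cross_entropy=cel, total=cel,
                         label=int(y[0]) if B == 1 else -1)
        return loss, grad_R

    def state_arrays(self):
        return self.linear.state_arrays()

    def load_state_arrays(self, state):
        self.linear.load_state_arrays(state)
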