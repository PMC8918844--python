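"""Class knowledge banks and their training objective.

A class knowledge bank (CKB) stores, for each of ``N`` classes, a set of
``M`` trainable ``D``-dimensional *knowledge units*.  The logit of class
``i`` for a representation ``r`` is the mean cosine similarity between
``r`` and the units of class ``i``:

    s_i = (1/M) * sum_j cos(u_ij, r)

Because each entry of ``s`` is a mean of cosines, logits live in
``[-1, 1]``; softmax over ``s`` therefore has a bounded maximum
probability of ``e^2 / (e^2 + N - 1)``.  Training minimizes a contrastive
term (pull the representation toward its own bank, push it away from the
mean of the others) plus the usual cross-entropy on the similarity
logits:

    L_con = -s_y + mean_{i != y} s_i
    L     = L_con + L_cel(s, y)

Everything here is plain NumPy with analytic gradients
(:func:`loss_and_grads`), so the head can be dropped behind any encoder
that produces a feature vector.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
from scipy.special import logsumexp

from .errors import (
    CheckpointError,
    ConfigurationError,
    DegenerateInputError,
    LabelError,
    ShapeError,
)

__all__ = [
    "ClassKnowledgeBank",
    "LossValue",
    "init_bank",
    "cosine_similarity",
    "class_similarity",
    "ckb_logits",
    "softmax_probabilities",
    "contrastive_loss",
    "cross_entropy_loss",
    "combined_loss",
    "predict_class",
    "loss_and_grads",
    "save_bank",
    "load_bank",
]

_CHECKPOINT_VERSION = "ckbank-bank-v1"


def _as_float_array(x, name: str) -> np.ndarray:
    arr = np.asarray(x, dtype=np.float64)
    if not np.all(np.isfinite(arr)):
        raise DegenerateInputError(f"{name} contains non-finite values")
    return arr


def _norms(v: np.ndarray, axis: int = -1) -> np.ndarray:
    """Euclidean norms along ``axis``; zero norm is a degenerate input."""
    n = np.linalg.norm(v, axis=axis)
    if np.any(n == 0.0):
        raise DegenerateInputError(
            "zero-norm vector fed to a cosine-similarity operation; "
            "refusing to define cos() for it"
        )
    return n


@dataclass(frozen=True)
class ClassKnowledgeBank:
    """The ``N x M x D`` tensor of knowledge units.

    Parameters
    ----------
    units
        Array of shape ``(n_classes, units_per_class, dim)``.  Unit
        ``u_ij`` is ``units[i, j]``.  Every unit must have strictly
        positive Euclidean norm.
    seed
        Seed used at initialization, kept for provenance (checkpoints
        store it); ``None`` for banks built from explicit arrays.
    """

    units: np.ndarray
    seed: int | None = None
    trainable: bool = field(default=True, compare=False)

    def __post_init__(self):
        units = _as_float_array(self.units, "units")
        if units.ndim != 3:
            raise ShapeError(
                f"bank units must be 3-d (N, M, D); got shape {units.shape}"
            )
        n, m, d = units.shape
        if n < 2:
            raise ConfigurationError(f"need at least 2 classes, got {n}")
        if m < 1 or d < 1:
            raise ConfigurationError(f"invalid bank shape {units.shape}")
        _norms(units)  # no zero units
        object.__setattr__(self, "units", units)

    @property
    def n_classes(self) -> int:
        return self.units.shape[0]

    @property
    def units_per_class(self) -> int:
        return self.units.shape[1]

    @property
    def dim(self) -> int:
        return self.units.shape[2]

    def with_units(self, units: np.ndarray) -> "ClassKnowledgeBank":
        """A bank with the same metadata but replaced unit tensor."""
        if units.shape != self.units.shape:
            raise ShapeError(
                f"replacement units {units.shape} != bank shape {self.units.shape}"
            )
        return ClassKnowledgeBank(units=units, seed=self.seed, trainable=self.trainable)

    def copy(self) -> "ClassKnowledgeBank":
        return self.with_units(self.units.copy())


@dataclass(frozen=True)
class LossValue:
    """Per-sample (or batch-mean) loss decomposition: total = contrastive + cross_entropy."""

    contrastive: float
    cross_entropy: float
    total: float
    label: int


def init_bank(
    n_classes: int, units_per_class: int, dim: int, seed: int
) -> ClassKnowledgeBank:
    """Randomly initialize a bank: i.i.d. standard normal units rescaled to unit norm.

    Unit norm is irrelevant to the cosine forward value but keeps the
    initial gradient scale uniform across units.  Identical seeds give
    bit-identical banks.
    """
    if n_classes < 2:
        raise ConfigurationError(f"need at least 2 classes, got {n_classes}")
    if units_per_class < 1 or dim < 1:
        raise ConfigurationError(
            f"units_per_class and dim must be >= 1, got {units_per_class}, {dim}"
        )
    rng = np.random.default_rng(seed)
    u = rng.standard_normal((n_classes, units_per_class, dim))
    u /= np.linalg.norm(u, axis=-1, keepdims=True)
    return ClassKnowledgeBank(units=u, seed=int(seed))


def cosine_similarity(u, r) -> float:
    """``u . r / (|u| |r|)`` for two equal-length vectors.

    Invariant under positive rescaling of either argument; raises
    :class:`DegenerateInputError` on zero-norm input rather than
    returning NaN.
    """
    u = _as_float_array(u, "u")
    r = _as_float_array(r, "r")
    if u.ndim != 1 or r.ndim != 1:
        raise ShapeError("cosine_similarity expects 1-d vectors")
    if u.shape != r.shape:
        raise ShapeError(f"length mismatch: {u.shape[0]} vs {r.shape[0]}")
    value = float(u @ r / (_norms(u) * _norms(r)))
    # guard against rounding just outside [-1, 1]
    return float(np.clip(value, -1.0, 1.0))


def class_similarity(bank_slice, r) -> float:
    """Mean cosine similarity between one class's ``M x D`` units and ``r``."""
    units = _as_float_array(bank_slice, "bank_slice")
    if units.ndim != 2 or units.shape[0] < 1:
        raise ShapeError("bank_slice must be a nonempty M x D array")
    return float(np.mean([cosine_similarity(u, r) for u in units]))


def _unit_directions(bank: ClassKnowledgeBank) -> np.ndarray:
    return bank.units / np.linalg.norm(bank.units, axis=-1, keepdims=True)


def ckb_logits(bank: ClassKnowledgeBank, r) -> np.ndarray:
    """Similarity logits ``s``: one mean cosine per class.

    ``r`` may be a single vector ``(D,)`` or a batch ``(B, D)``; output is
    ``(N,)`` or ``(B, N)`` accordingly, each row depending only on its own
    input row.
    """
    r = _as_float_array(r, "r")
    single = r.ndim == 1
    R = r[None, :] if single else r
    if R.ndim != 2 or R.shape[1] != bank.dim:
        raise ShapeError(
            f"representation dim {R.shape[-1] if R.ndim else '?'} != bank dim {bank.dim}"
        )
    r_hat = R / _norms(R)[:, None]
    u_hat = _unit_directions(bank)
    s = np.einsum("nmd,bd->bn", u_hat, r_hat) / bank.units_per_class
    s = np.clip(s, -1.0, 1.0)
    return s[0] if single else s


def softmax_probabilities(s) -> np.ndarray:
    """Softmax over similarity logits, stabilized by subtracting the row max."""
    s = np.asarray(s, dtype=np.float64)
    if not np.all(np.isfinite(s)):
        raise DegenerateInputError("non-finite logits")
    z = s - np.max(s, axis=-1, keepdims=True)
    e = np.exp(z)
    return e / np.sum(e, axis=-1, keepdims=True)


def _check_label(bank: ClassKnowledgeBank, y) -> np.ndarray:
    y = np.asarray(y)
    if not np.issubdtype(y.dtype, np.integer):
        yf = np.asarray(y, dtype=np.float64)
        if not np.all(yf == np.round(yf)):
            raise LabelError(f"labels must be integers, got {y!r}")
        y = yf.astype(np.int64)
    if np.any(y < 0) or np.any(y >= bank.n_classes):
        raise LabelError(
            f"label out of range for {bank.n_classes}-class bank: {y!r}"
        )
    return y


def contrastive_loss(bank: ClassKnowledgeBank, r, y):
    """``-s_y + mean_{i != y} s_i``; bounded in ``[-2, 2]``.

    Accepts a single representation with an int label, or a batch with a
    label vector (returns the per-sample array).
    """
    s = ckb_logits(bank, r)
    y = _check_label(bank, y)
    single = s.ndim == 1
    S = s[None, :] if single else s
    Y = np.atleast_1d(y)
    n = bank.n_classes
    s_y = S[np.arange(len(Y)), Y]
    others = (S.sum(axis=1) - s_y) / (n - 1)
    out = -s_y + others
    return float(out[0]) if single else out


def cross_entropy_loss(s, y) -> np.ndarray:
    """``-log p_y`` computed from logits via log-sum-exp."""
    s = np.asarray(s, dtype=np.float64)
    single = s.ndim == 1
    S = s[None, :] if single else s
    Y = np.atleast_1d(np.asarray(y, dtype=np.int64))
    ce = logsumexp(S, axis=1) - S[np.arange(len(Y)), Y]
    return float(ce[0]) if single else ce


def combined_loss(bank: ClassKnowledgeBank, r, y: int) -> LossValue:
    """Contrastive plus cross-entropy loss for one representation."""
    y_arr = _check_label(bank, y)
    if y_arr.ndim != 0:
        raise LabelError("combined_loss is per-sample; use loss_and_grads for batches")
    s = ckb_logits(bank, r)
    con = contrastive_loss(bank, r, int(y_arr))
    cel = cross_entropy_loss(s, int(y_arr))
    return LossValue(
        contrastive=con, cross_entropy=cel, total=con + cel, label=int(y_arr)
    )


def predict_class(bank: ClassKnowledgeBank, r):
    """Argmax over similarity logits; ties break to the lowest class index.

    Identical to argmax over softmax probabilities (softmax is strictly
    monotone).  Batched input gives a label vector.
    """
    s = ckb_logits(bank, r)
    return int(np.argmax(s)) if s.ndim == 1 else np.argmax(s, axis=1)


def loss_and_grads(bank: ClassKnowledgeBank, R, y):
    """Batch-mean combined loss with analytic gradients.

    Parameters
    ----------
    R
        Representations, shape ``(B, D)`` (a single ``(D,)`` vector is
        promoted to a batch of one).
    y
        Integer labels, shape ``(B,)``.

    Returns
    -------
    loss : LossValue
        Batch means of the contrastive, cross-entropy and total loss
        (``label`` is -1 for batches larger than one).
    grad_units : ndarray, shape (N, M, D)
        Gradient of the mean total loss with respect to every unit.
    grad_R : ndarray, shape (B, D)
        Gradient with respect to each representation.

    Notes
    -----
    With ``c = cos(u, r)``, ``∂c/∂u = (r_hat - c u_hat)/|u|`` and
    symmetrically for ``r``.  Both loss terms act through the logits, so
    the chain rule only needs ``∂L/∂s_i``, which is
    ``softmax(s)_i - 1[i=y]`` for the cross-entropy and
    ``-1[i=y] + (1 - 1[i=y])/(N-1)`` for the contrastive term.
    """
    R = _as_float_array(R, "R")
    single = R.ndim == 1
    if single:
        R = R[None, :]
    if R.ndim != 2 or R.shape[1] != bank.dim:
        raise ShapeError(f"R must be (B, {bank.dim}); got {R.shape}")
    y = np.atleast_1d(_check_label(bank, y))
    if len(y) != len(R):
        raise ShapeError(f"batch size mismatch: {len(R)} representations, {len(y)} labels")

    B = len(R)
    N, M, D = bank.units.shape
    u_norm = np.linalg.norm(bank.units, axis=-1)  # (N, M)
    u_hat = bank.units / u_norm[..., None]
    r_norm = _norms(R)
    r_hat = R / r_norm[:, None]

    cos = np.einsum("nmd,bd->bnm", u_hat, r_hat)  # (B, N, M)
    s = cos.mean(axis=2)  # (B, N)
    p = softmax_probabilities(s)

    onehot = np.zeros((B, N))
    onehot[np.arange(B), y] = 1.0
    s_y = s[np.arange(B), y]
    con = -s_y + (s.sum(axis=1) - s_y) / (N - 1)
    cel = logsumexp(s, axis=1) - s_y

    # dL/ds per sample: cross-entropy part + contrastive part
    g_s = (p - onehot) + (-onehot + (1.0 - onehot) / (N - 1))  # (B, N)

    # per-unit coefficient, including the 1/M of the mean and the 1/B of
    # the batch mean
    coef = g_s[:, :, None] / (M * B)  # (B, N, M)

    # grad wrt units: sum over batch of coef * (r_hat - cos*u_hat)/|u|
    grad_units = (
        np.einsum("bnm,bd->nmd", coef, r_hat)
        - np.einsum("bnm,bnm->nm", coef, cos)[..., None] * u_hat
    ) / u_norm[..., None]

    # grad wrt each representation: sum over units of coef * (u_hat - cos*r_hat)/|r|
    grad_R = (
        np.einsum("bnm,nmd->bd", coef, u_hat)
        - np.einsum("bnm,bnm->b", coef, cos)[:, None] * r_hat
    ) / r_norm[:, None]

    loss = LossValue(
        contrastive=float(con.mean()),
        cross_entropy=float(cel.mean()),
        total=float((con + cel).mean()),
        label=int(y[0]) if B == 1 else -1,
    )
    return loss, grad_units, grad_R


def save_bank(bank: ClassKnowledgeBank, path) -> None:
    """Write a checkpoint bundle; round-trip is bit-exact."""
    meta = {
        "format": _CHECKPOINT_VERSION,
        "n_classes": bank.n_classes,
        "units_per_class": bank.units_per_class,
        "dim": bank.dim,
        "seed": bank.seed,
    }
    np.savez(path, units=bank.units, meta=np.bytes_(json.dumps(meta).encode()))


def load_bank(path) -> ClassKnowledgeBank:
    with np.load(path) as data:
        if "meta" not in data or "units" not in data:
            raise CheckpointError(f"not a bank checkpoint: {path}")
        meta = json.loads(bytes(data["meta"]).decode())
        if meta.get("format") != _CHECKPOINT_VERSION:
            raise CheckpointError(f"unknown checkpoint format {meta.get('format')!r}")
        units = data["units"]
    if units.shape != (meta["n_classes"], meta["units_per_class"], meta["dim"]):
        raise CheckpointError("checkpoint metadata disagrees with unit tensor shape")
    return ClassKnowledgeBank(units=units, seed=meta["seed"])
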