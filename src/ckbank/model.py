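"""Full classifier: encoder + projection head + classification head.

`CKBModel` bundles the three stages, handles checkpointing (a single
``.npz`` with every parameter tensor, the normalization running
statistics, and a JSON metadata block), and offers scikit-learn-style
``fit`` / ``predict`` / ``predict_proba``.
"""

from __future__ import annotations

import json

import numpy as np

from .bank import init_bank, softmax_probabilities
from .errors import CheckpointError, ConfigurationError
from .heads import BankHead, LinearHead
from .network import EncoderSpec, ProjectionHead, ProjectionHeadSpec, build_encoder
from .training import TrainingConfig, TrainingHistory, train_head

_CHECKPOINT_VERSION = "ckbank-model-v1"


class CKBModel:
    """Encoder → projection head → (bank | linear) head."""

    def __init__(self, encoder_spec: EncoderSpec, projection_spec: ProjectionHeadSpec,
                 head, config: TrainingConfig, seed: int):
        self.encoder_spec = encoder_spec
        self.projection_spec = projection_spec
        self.encoder = build_encoder(encoder_spec, seed=seed)
        self.projection = ProjectionHead(projection_spec, seed=seed + 1)
        self.head = head
        self.config = config
        self.seed = seed

    # -- construction ----------------------------------------------------

    @classmethod
    def build(cls, input_shape: tuple[int, ...], n_classes: int,
              config: TrainingConfig | None = None, *, encoder_kind: str = "identity",
              head_kind: str = "ckb", encoder_dim: int = 64,
              projection_bypass: bool = False, hidden_dim: int | None = None,
              encoder_trainable: bool = False) -> "CKBModel":
        """Assemble a fresh model for data of the given shape.

        ``input_shape`` is ``(features,)`` for vector data (identity
        encoder) or ``(3, H, W)`` for images (tiny_conv encoder).  With
        ``projection_bypass`` the banks act directly on the encoder
        output (the feature-space test harness), which forces
        ``dim == D0``.
        """
        config = config or TrainingConfig()
        if encoder_kind == "identity":
            d0 = input_shape[0]
        else:
            d0 = encoder_dim
        enc_spec = EncoderSpec(kind=encoder_kind, input_shape=tuple(input_shape),
                               output_dim=d0, trainable=encoder_trainable)
        dim = d0 if projection_bypass else config.dim
        if projection_bypass and config.dim != d0:
            config = config.replace(dim=d0)
        proj_spec = ProjectionHeadSpec(
            input_dim=d0, output_dim=dim,
            hidden_dim=hidden_dim if hidden_dim is not None else min(512, max(32, 4 * dim)),
            bypass=projection_bypass,
        )
        if head_kind == "ckb":
            head = BankHead(init_bank(n_classes, config.units_per_class, dim,
                                      seed=config.seed))
        elif head_kind == "linear":
            head = LinearHead(dim, n_classes, seed=config.seed)
        else:
            raise ConfigurationError(f"unknown head kind {head_kind!r}")
        return cls(enc_spec, proj_spec, head, config, seed=config.seed)

    # -- inference -------------------------------------------------------

    def representations(self, X, train: bool = False) -> np.ndarray:
        r0 = self.encoder.forward(np.asarray(X, dtype=np.float64))
        return self.projection.forward(r0, train=train)

    def logits(self, X) -> np.ndarray:
        return self.head.logits(self.representations(X))

    def predict_proba(self, X) -> np.ndarray:
        return softmax_probabilities(self.logits(X))

    def predict(self, X) -> np.ndarray:
        return np.argmax(self.logits(X), axis=-1)

    # -- training --------------------------------------------------------

    def fit(self, X, y) -> TrainingHistory:
        return train_head(self.head, self.encoder, self.projection,
                          np.asarray(X, dtype=np.float64), np.asarray(y), self.config)

    # -- checkpointing ---------------------------------------------------

    def save(self, path) -> None:
        arrays: dict[str, np.ndarray] = {}
        arrays.update(self.encoder.state_arrays())
        arrays.update(self.projection.state_arrays())
        if isinstance(self.head, BankHead):
            arrays["bank.units"] = self.head.units.value
        else:
            arrays.update(self.head.state_arrays())
        meta = {
            "format": _CHECKPOINT_VERSION,
            "encoder_spec": {
                "kind": self.encoder_spec.kind,
                "input_shape": list(self.encoder_spec.input_shape),
                "output_dim": self.encoder_spec.output_dim,
                "trainable": self.encoder_spec.trainable,
            },
            "projection_spec": {
                "input_dim": self.projection_spec.input_dim,
                "output_dim": self.projection_spec.output_dim,
                "hidden_dim": self.projection_spec.hidden_dim,
                "affine": self.projection_spec.affine,
                "bypass": self.projection_spec.bypass,
                "use_norm": self.projection_spec.use_norm,
            },
            "head": {
                "kind": self.head.kind,
                "n_classes": self.head.n_classes,
                "units_per_class": (self.head.units.value.shape[1]
                                    if isinstance(self.head, BankHead) else None),
                "init_seed": getattr(self.head, "init_seed", None),
            },
            "config": self.config.to_dict(),
            "seed": self.seed,
        }
        np.savez(path, __meta__=np.bytes_(json.dumps(meta).encode()), **arrays)

    @classmethod
    def load(cls, path) -> "CKBModel":
        with np.load(path) as data:
            if "__meta__" not in data:
                raise CheckpointError(f"not a model checkpoint: {path}")
            meta = json.loads(bytes(data["__meta__"]).decode())
            if meta.get("format") != _CHECKPOINT_VERSION:
                raise CheckpointError(f"unknown checkpoint format {meta.get('format')!r}")
            arrays = {k: data[k] for k in data.files if k != "__meta__"}

        es = meta["encoder_spec"]
        enc_spec = EncoderSpec(kind=es["kind"], input_shape=tuple(es["input_shape"]),
                               output_dim=es["output_dim"], trainable=es["trainable"])
        ps = meta["projection_spec"]
        proj_spec = ProjectionHeadSpec(**ps)
        config = TrainingConfig(**meta["config"])
        hm = meta["head"]
        if hm["kind"] == "ckb":
            dim = proj_spec.output_dim
            head = BankHead(init_bank(hm["n_classes"], hm["units_per_class"] or 1,
                                      dim, seed=0))
            head.units.value = np.asarray(arrays["bank.units"], dtype=np.float64)
            head.units.grad = np.zeros_like(head.units.value)
            head.init_seed = hm["init_seed"]
        else:
            head = LinearHead(proj_spec.output_dim, hm["n_classes"], seed=0)
            head.load_state_arrays(arrays)
        model = cls(enc_spec, proj_spec, head, config, seed=meta["seed"])
        model.encoder.load_state_arrays(arrays)
        model.projection.load_state_arrays(arrays)
        return model
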