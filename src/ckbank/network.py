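"""Encoders and the projection head, in plain NumPy.

The pipeline is ``r0 = encoder(x)`` followed by ``r = projection(r0)``;
``r`` is the representation compared against the knowledge banks.  Two
self-contained encoders are provided:

``identity``
    passes feature vectors through unchanged (for tabular/feature
    experiments and for tests that exercise the head in isolation);
``tiny_conv``
    a small convolutional network (three 3x3 conv + ReLU + 2x average
    pooling blocks, then global average pooling) for the synthetic image
    experiments.  It is deliberately minimal: the design assumes the
    heavy lifting is done by the projection head and the banks, mirroring
    a frozen-encoder regime.

The projection head is a three-linear-layer MLP; the first two linear
layers are followed by batch normalization and ReLU, the last by batch
normalization alone.

Every layer implements ``forward`` and ``backward`` with hand-derived
gradients; :mod:`ckbank.training` validates them end to end against
finite differences.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

from .errors import ConfigurationError, ShapeError, UninitializedStatisticsError

__all__ = [
    "Parameter",
    "Module",
    "Linear",
    "BatchNorm1d",
    "ReLU",
    "EncoderSpec",
    "ProjectionHeadSpec",
    "IdentityEncoder",
    "TinyConvEncoder",
    "ProjectionHead",
    "build_encoder",
    "encode",
    "project",
]


class Parameter:
    """A trainable array with an accumulated gradient.

    ``decay`` marks whether decoupled weight decay applies (true for
    weight matrices and bank units, false for biases and normalization
    scale/shift).
    """

    __slots__ = ("value", "grad", "decay", "name")

    def __init__(self, value: np.ndarray, decay: bool, name: str):
        self.value = np.asarray(value, dtype=np.float64)
        self.grad = np.zeros_like(self.value)
        self.decay = decay
        self.name = name

    def zero_grad(self) -> None:
        self.grad.fill(0.0)


class Module:
    """Minimal layer base: parameter registry plus train/eval mode."""

    def parameters(self) -> list[Parameter]:
        return []

    def zero_grad(self) -> None:
        for p in self.parameters():
            p.zero_grad()

    def state_arrays(self) -> dict[str, np.ndarray]:
        """All arrays needed to restore the module bit-exactly."""
        return {p.name: p.value for p in self.parameters()}

    def load_state_arrays(self, state: dict[str, np.ndarray]) -> None:
        for p in self.parameters():
            p.value = np.asarray(state[p.name], dtype=np.float64).reshape(p.value.shape)
            p.grad = np.zeros_like(p.value)


class Linear(Module):
    def __init__(self, in_dim: int, out_dim: int, rng: np.random.Generator, name: str):
        scale = np.sqrt(2.0 / in_dim)
        self.W = Parameter(rng.standard_normal((out_dim, in_dim)) * scale, True, f"{name}.W")
        self.b = Parameter(np.zeros(out_dim), False, f"{name}.b")
        self._x: np.ndarray | None = None

    def parameters(self):
        return [self.W, self.b]

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._x = x
        return x @ self.W.value.T + self.b.value

    def backward(self, g: np.ndarray) -> np.ndarray:
        self.W.grad += g.T @ self._x
        self.b.grad += g.sum(axis=0)
        return g @ self.W.value


class ReLU(Module):
    def __init__(self):
        self._mask: np.ndarray | None = None

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._mask = x > 0
        return x * self._mask

    def backward(self, g: np.ndarray) -> np.ndarray:
        return g * self._mask


class BatchNorm1d(Module):
    """Per-feature batch normalization with learnable scale/shift.

    Training mode normalizes with batch statistics and updates running
    statistics (exponential moving average, momentum 0.1).  Evaluation
    mode uses the running statistics, so single-sample inference is well
    defined — but only after at least one training batch has been seen;
    otherwise an :class:`UninitializedStatisticsError` is raised.
    """

    def __init__(self, dim: int, name: str, affine: bool = True, momentum: float = 0.1,
                 eps: float = 1e-5):
        self.gamma = Parameter(np.ones(dim), False, f"{name}.gamma")
        self.beta = Parameter(np.zeros(dim), False, f"{name}.beta")
        self.affine = affine
        self.momentum = momentum
        self.eps = eps
        self.running_mean = np.zeros(dim)
        self.running_var = np.ones(dim)
        self.initialized = False
        self._cache = None

    def parameters(self):
        return [self.gamma, self.beta] if self.affine else []

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        if train:
            mean = x.mean(axis=0)
            var = x.var(axis=0)
            n = x.shape[0]
            unbiased = var * n / (n - 1) if n > 1 else var
            m = self.momentum
            if not self.initialized:
                self.running_mean = mean.copy()
                self.running_var = unbiased.copy()
                self.initialized = True
            else:
                self.running_mean = (1 - m) * self.running_mean + m * mean
                self.running_var = (1 - m) * self.running_var + m * unbiased
        else:
            if not self.initialized:
                raise UninitializedStatisticsError(
                    "batch-norm evaluation requested before any training "
                    "statistics were accumulated"
                )
            mean, var = self.running_mean, self.running_var
        std = np.sqrt(var + self.eps)
        xhat = (x - mean) / std
        self._cache = (xhat, std, train)
        out = xhat
        if self.affine:
            out = self.gamma.value * xhat + self.beta.value
        return out

    def backward(self, g: np.ndarray) -> np.ndarray:
        xhat, std, train = self._cache
        if self.affine:
            self.gamma.grad += (g * xhat).sum(axis=0)
            self.beta.grad += g.sum(axis=0)
            g = g * self.gamma.value
        if not train:
            return g / std
        # batch statistics participated in the forward pass
        return (g - g.mean(axis=0) - xhat * (g * xhat).mean(axis=0)) / std

    def state_arrays(self):
        state = super().state_arrays()
        state[f"{self.gamma.name[:-6]}.running_mean"] = self.running_mean
        state[f"{self.gamma.name[:-6]}.running_var"] = self.running_var
        state[f"{self.gamma.name[:-6]}.initialized"] = np.array([self.initialized])
        return state

    def load_state_arrays(self, state):
        super().load_state_arrays(state)
        prefix = self.gamma.name[:-6]
        self.running_mean = np.asarray(state[f"{prefix}.running_mean"], dtype=np.float64)
        self.running_var = np.asarray(state[f"{prefix}.running_var"], dtype=np.float64)
        self.initialized = bool(np.asarray(state[f"{prefix}.initialized"]).ravel()[0])


class Conv2d(Module):
    """3x3 same-padding convolution (stride 1) via sliding windows."""

    def __init__(self, in_ch: int, out_ch: int, rng: np.random.Generator, name: str,
                 kernel: int = 3):
        if kernel % 2 != 1:
            raise ConfigurationError("odd kernel sizes only")
        scale = np.sqrt(2.0 / (in_ch * kernel * kernel))
        self.W = Parameter(
            rng.standard_normal((out_ch, in_ch, kernel, kernel)) * scale, True, f"{name}.W"
        )
        self.b = Parameter(np.zeros(out_ch), False, f"{name}.b")
        self.kernel = kernel
        self._win: np.ndarray | None = None

    def parameters(self):
        return [self.W, self.b]

    def _windows(self, x: np.ndarray) -> np.ndarray:
        pad = self.kernel // 2
        xp = np.pad(x, ((0, 0), (0, 0), (pad, pad), (pad, pad)))
        return sliding_window_view(xp, (self.kernel, self.kernel), axis=(2, 3))

    def forward(self, x: np.ndarray) -> np.ndarray:
        win = self._windows(x)  # (B, C, H, W, k, k)
        self._win = win
        return np.einsum("bchwij,ocij->bohw", win, self.W.value) + self.b.value[:, None, None]

    def backward(self, g: np.ndarray) -> np.ndarray:
        self.W.grad += np.einsum("bohw,bchwij->ocij", g, self._win)
        self.b.grad += g.sum(axis=(0, 2, 3))
        # dx = "full" correlation of g with the kernel rotated 180 degrees
        pad = self.kernel // 2
        gp = np.pad(g, ((0, 0), (0, 0), (pad, pad), (pad, pad)))
        gwin = sliding_window_view(gp, (self.kernel, self.kernel), axis=(2, 3))
        W_rot = self.W.value[:, :, ::-1, ::-1]
        return np.einsum("bohwij,ocij->bchw", gwin, W_rot)


class AvgPool2d(Module):
    """2x2 average pooling with stride 2; odd trailing rows/cols are cropped."""

    def __init__(self):
        self._in_shape = None

    def forward(self, x: np.ndarray) -> np.ndarray:
        B, C, H, W = x.shape
        H2, W2 = H // 2 * 2, W // 2 * 2
        x = x[:, :, :H2, :W2]
        self._in_shape = (B, C, H, W)
        return x.reshape(B, C, H2 // 2, 2, W2 // 2, 2).mean(axis=(3, 5))

    def backward(self, g: np.ndarray) -> np.ndarray:
        B, C, H, W = self._in_shape
        out = np.zeros((B, C, H, W))
        up = np.repeat(np.repeat(g, 2, axis=2), 2, axis=3) / 4.0
        out[:, :, : up.shape[2], : up.shape[3]] = up
        return out


@dataclass(frozen=True)
class EncoderSpec:
    """What produces the pre-projection representation ``r0``.

    ``identity`` requires vector input of width ``output_dim``;
    ``tiny_conv`` accepts square RGB images of side >= 16.
    """

    kind: str
    input_shape: tuple[int, ...]
    output_dim: int
    trainable: bool = False

    def __post_init__(self):
        if self.kind not in ("identity", "tiny_conv"):
            raise ConfigurationError(f"unknown encoder kind {self.kind!r}")
        if self.kind == "identity":
            if len(self.input_shape) != 1:
                raise ConfigurationError("identity encoder takes vector input")
            if self.input_shape[0] != self.output_dim:
                raise ConfigurationError(
                    "identity encoder output_dim must equal the feature count"
                )
        else:
            if len(self.input_shape) != 3:
                raise ConfigurationError("tiny_conv takes (channels, height, width) input")
            c, h, w = self.input_shape
            if c != 3 or h != w or h < 16:
                raise ConfigurationError(
                    "tiny_conv requires square RGB input of side >= 16"
                )


class IdentityEncoder(Module):
    def __init__(self, spec: EncoderSpec):
        self.spec = spec

    def forward(self, x: np.ndarray) -> np.ndarray:
        if x.ndim != 2 or x.shape[1] != self.spec.output_dim:
            raise ShapeError(
                f"identity encoder expects (B, {self.spec.output_dim}); got {x.shape}"
            )
        return x

    def backward(self, g: np.ndarray) -> np.ndarray:
        return g


class TinyConvEncoder(Module):
    """Three conv blocks then global average pooling to ``output_dim`` channels."""

    CHANNELS = (16, 32)

    def __init__(self, spec: EncoderSpec, seed: int):
        self.spec = spec
        rng = np.random.default_rng(seed)
        c1, c2 = self.CHANNELS
        self.conv1 = Conv2d(3, c1, rng, "enc.conv1")
        self.conv2 = Conv2d(c1, c2, rng, "enc.conv2")
        self.conv3 = Conv2d(c2, spec.output_dim, rng, "enc.conv3")
        self.relu1, self.relu2, self.relu3 = ReLU(), ReLU(), ReLU()
        self.pool1, self.pool2, self.pool3 = AvgPool2d(), AvgPool2d(), AvgPool2d()
        self._gap_hw: tuple[int, int] | None = None

    def parameters(self):
        if not self.spec.trainable:
            return []
        return self.conv1.parameters() + self.conv2.parameters() + self.conv3.parameters()

    def all_parameters(self):
        """Parameters regardless of the trainable flag (for checkpoints)."""
        return self.conv1.parameters() + self.conv2.parameters() + self.conv3.parameters()

    def forward(self, x: np.ndarray) -> np.ndarray:
        c, h, w = self.spec.input_shape
        if x.ndim != 4 or x.shape[1:] != (c, h, w):
            raise ShapeError(f"tiny_conv expects (B, {c}, {h}, {w}); got {x.shape}")
        z = self.pool1.forward(self.relu1.forward(self.conv1.forward(x)))
        z = self.pool2.forward(self.relu2.forward(self.conv2.forward(z)))
        z = self.pool3.forward(self.relu3.forward(self.conv3.forward(z)))
        self._gap_hw = z.shape[2:]
        return z.mean(axis=(2, 3))

    def backward(self, g: np.ndarray) -> np.ndarray:
        h, w = self._gap_hw
        gz = np.broadcast_to(g[:, :, None, None], g.shape + (h, w)) / (h * w)
        gz = self.conv3.backward(self.relu3.backward(self.pool3.backward(gz)))
        gz = self.conv2.backward(self.relu2.backward(self.pool2.backward(gz)))
        return self.conv1.backward(self.relu1.backward(self.pool1.backward(gz)))

    def state_arrays(self):
        state = {}
        for p in self.all_parameters():
            state[p.name] = p.value
        return state

    def load_state_arrays(self, state):
        for p in self.all_parameters():
            p.value = np.asarray(state[p.name], dtype=np.float64).reshape(p.value.shape)
            p.grad = np.zeros_like(p.value)


def build_encoder(spec: EncoderSpec, seed: int = 0) -> Module:
    if spec.kind == "identity":
        return IdentityEncoder(spec)
    return TinyConvEncoder(spec, seed)


def encode(encoder: Module, x: np.ndarray) -> np.ndarray:
    """Run the encoder on a batch, returning ``r0`` of shape ``(B, D0)``."""
    return encoder.forward(np.asarray(x, dtype=np.float64))


@dataclass(frozen=True)
class ProjectionHeadSpec:
    """Three linear layers; BN + ReLU after the first two, BN alone after the last.

    ``bypass`` turns the head into the identity map (requires
    ``input_dim == output_dim``): a test affordance that lets the banks
    operate directly on raw features.  ``use_norm=False`` likewise
    disables the normalization layers for constructed-weight tests.
    """

    input_dim: int
    output_dim: int
    hidden_dim: int = 512
    affine: bool = True
    bypass: bool = False
    use_norm: bool = True

    def __post_init__(self):
        if min(self.input_dim, self.output_dim, self.hidden_dim) < 1:
            raise ConfigurationError("projection dimensions must be >= 1")
        if self.bypass and self.input_dim != self.output_dim:
            raise ConfigurationError("bypass requires input_dim == output_dim")


class ProjectionHead(Module):
    def __init__(self, spec: ProjectionHeadSpec, seed: int = 0):
        self.spec = spec
        rng = np.random.default_rng(seed)
        if spec.bypass:
            self._layers = []
            return
        self.l1 = Linear(spec.input_dim, spec.hidden_dim, rng, "proj.l1")
        self.l2 = Linear(spec.hidden_dim, spec.hidden_dim, rng, "proj.l2")
        self.l3 = Linear(spec.hidden_dim, spec.output_dim, rng, "proj.l3")
        self.bn1 = BatchNorm1d(spec.hidden_dim, "proj.bn1", affine=spec.affine)
        self.bn2 = BatchNorm1d(spec.hidden_dim, "proj.bn2", affine=spec.affine)
        self.bn3 = BatchNorm1d(spec.output_dim, "proj.bn3", affine=spec.affine)
        self.relu1, self.relu2 = ReLU(), ReLU()
        self._layers = [self.l1, self.bn1, self.l2, self.bn2, self.l3, self.bn3]

    def parameters(self):
        return [p for layer in self._layers for p in layer.parameters()]

    def forward(self, r0: np.ndarray, train: bool = False) -> np.ndarray:
        if self.spec.bypass:
            return r0
        if r0.ndim != 2 or r0.shape[1] != self.spec.input_dim:
            raise ShapeError(
                f"projection expects (B, {self.spec.input_dim}); got {r0.shape}"
            )
        use_norm = self.spec.use_norm
        z = self.l1.forward(r0)
        if use_norm:
            z = self.bn1.forward(z, train)
        z = self.relu1.forward(z)
        z = self.l2.forward(z)
        if use_norm:
            z = self.bn2.forward(z, train)
        z = self.relu2.forward(z)
        z = self.l3.forward(z)
        if use_norm:
            z = self.bn3.forward(z, train)
        return z

    def backward(self, g: np.ndarray) -> np.ndarray:
        if self.spec.bypass:
            return g
        use_norm = self.spec.use_norm
        if use_norm:
            g = self.bn3.backward(g)
        g = self.l3.backward(g)
        g = self.relu2.backward(g)
        if use_norm:
            g = self.bn2.backward(g)
        g = self.l2.backward(g)
        g = self.relu1.backward(g)
        if use_norm:
            g = self.bn1.backward(g)
        return self.l1.backward(g)

    def state_arrays(self):
        state = {}
        for layer in self._layers:
            state.update(layer.state_arrays())
        return state

    def load_state_arrays(self, state):
        for layer in self._layers:
            layer.load_state_arrays(state)


def project(head: ProjectionHead, r0: np.ndarray, train: bool = False) -> np.ndarray:
    """Apply the projection head, yielding representations ``r`` of width D."""
    return head.forward(np.asarray(r0, dtype=np.float64), train=train)
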