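"""Synthetic data with controllable class structure and imbalance.

Two generators make every other module testable without any download:

* **Gaussian feature clusters** — labels drawn from configurable class
  priors, features from isotropic Gaussians around per-class means.
  Because the clusters are isotropic, the two-class equal-prior Bayes
  error has the closed form ``Phi(-delta / (2 sigma))`` for mean
  separation ``delta`` and dispersion ``sigma``, which anchors the
  end-to-end training tests to an exact optimum.

* **Class-conditional images** — a textured skin-toned background with a
  central wound-like blob whose hue, saturation and granularity depend
  on the label.  The binary preset echoes the qualitative cues of ulcer
  photographs: the positive class gets a yellowish, granular, "secreting"
  blob, the negative class a cleaner, paler, smoother one.  No clinical
  realism is claimed; the point is a controllable visual signal.
  ``cue_strength`` interpolates between "no class signal at all" (0: the
  two classes are identically distributed) and the full cue (1).

Prior presets mirror a realistic imbalance range: ``infection``
(628:831, mild) and ``ischaemia`` (1,249:210, roughly 6:1).
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from matplotlib.colors import hsv_to_rgb

from .errors import ConfigurationError

__all__ = ["SyntheticSpec", "PRIOR_PRESETS", "generate_features", "generate_images",
           "bayes_error_two_class", "write_image_dataset"]

PRIOR_PRESETS: dict[str, tuple[float, float]] = {
    "balanced": (0.5, 0.5),
    "infection": (628 / 1459, 831 / 1459),
    "ischaemia": (1249 / 1459, 210 / 1459),
}


@dataclass(frozen=True)
class SyntheticSpec:
    """Parameters of the generators; validated on construction."""

    n_classes: int = 2
    class_priors: tuple[float, ...] = (0.5, 0.5)
    feature_dim: int = 8
    class_means: np.ndarray | None = None
    dispersion: float = 1.0
    image_mode: bool = False
    image_size: int = 32
    cue_strength: float = 1.0
    seed: int = 0

    def __post_init__(self):
        if self.n_classes < 2:
            raise ConfigurationError("need at least 2 classes")
        priors = np.asarray(self.class_priors, dtype=np.float64)
        if priors.shape != (self.n_classes,) or np.any(priors < 0):
            raise ConfigurationError("class_priors must be a nonnegative vector of length N")
        if not np.isclose(priors.sum(), 1.0, atol=1e-8):
            raise ConfigurationError(f"class priors must sum to 1, got {priors.sum()}")
        if self.dispersion <= 0:
            raise ConfigurationError("dispersion must be positive")
        if self.image_mode:
            if self.image_size < 16:
                raise ConfigurationError("image_size must be >= 16")
            if not 0.0 <= self.cue_strength <= 1.0:
                raise ConfigurationError("cue_strength must lie in [0, 1]")
        else:
            means = self.class_means
            if means is None:
                means = _default_means(self.n_classes, self.feature_dim, separation=4.0)
            means = np.asarray(means, dtype=np.float64)
            if means.shape != (self.n_classes, self.feature_dim):
                raise ConfigurationError(
                    f"class_means must be {self.n_classes} x {self.feature_dim}"
                )
            object.__setattr__(self, "class_means", means)
        object.__setattr__(self, "class_priors", tuple(float(p) for p in priors))

    def replace(self, **kw) -> "SyntheticSpec":
        return replace(self, **kw)

    @classmethod
    def gaussian(cls, n_classes: int = 2, separation: float = 4.0,
                 dispersion: float = 1.0, priors: str | tuple = "balanced",
                 feature_dim: int = 8, seed: int = 0) -> "SyntheticSpec":
        """Feature-cluster spec with pairwise mean distance ``separation``."""
        if isinstance(priors, str):
            priors = PRIOR_PRESETS[priors]
        return cls(
            n_classes=n_classes, class_priors=tuple(priors), feature_dim=feature_dim,
            class_means=_default_means(n_classes, feature_dim, separation),
            dispersion=dispersion, seed=seed,
        )

    @classmethod
    def images(cls, image_size: int = 32, cue_strength: float = 1.0,
               priors: str | tuple = "balanced", seed: int = 0) -> "SyntheticSpec":
        if isinstance(priors, str):
            priors = PRIOR_PRESETS[priors]
        return cls(
            n_classes=2, class_priors=tuple(priors), image_mode=True,
            image_size=image_size, cue_strength=cue_strength, seed=seed,
        )


def _default_means(n_classes: int, dim: int, separation: float) -> np.ndarray:
    """Class means with every pairwise distance equal to ``separation``.

    Two classes sit at ``-/+ separation/2`` on the first axis; more
    classes use scaled one-hot corners (pairwise distance
    ``separation``).
    """
    if dim < n_classes - 1:
        raise ConfigurationError("feature_dim too small for the requested class count")
    means = np.zeros((n_classes, dim))
    if n_classes == 2:
        means[0, 0] = -separation / 2
        means[1, 0] = +separation / 2
    else:
        for i in range(n_classes):
            means[i, i % dim] = separation / np.sqrt(2)
    return means


def bayes_error_two_class(separation: float, dispersion: float) -> float:
    """Optimal error for two equal-prior isotropic Gaussians: ``Phi(-delta/(2 sigma))``."""
    from scipy.stats import norm

    return float(norm.cdf(-separation / (2.0 * dispersion)))


def generate_features(spec: SyntheticSpec, n: int, seed: int | None = None):
    """Labeled Gaussian-cluster features.

    Returns ``(X, y)`` with ``X`` of shape ``(n, feature_dim)``.
    Deterministic for a fixed seed (``spec.seed`` unless overridden).
    """
    if spec.image_mode:
        raise ConfigurationError("spec is an image spec; use generate_images")
    if n < 1:
        raise ConfigurationError("n must be >= 1")
    rng = np.random.default_rng(spec.seed if seed is None else seed)
    y = rng.choice(spec.n_classes, size=n, p=np.asarray(spec.class_priors))
    X = spec.class_means[y] + spec.dispersion * rng.standard_normal((n, spec.feature_dim))
    return X, y


# -- image generator ---------------------------------------------------------

# Blob appearance in HSV plus a granular-noise amplitude.  ``neutral`` is
# what every class looks like at cue_strength 0; the per-class entries
# are the full-cue targets.  Class 1 ("infected"): yellow, saturated,
# granular.  Class 0 ("clean"): pale pink, smooth.
_NEUTRAL = {"hue": 0.05, "sat": 0.45, "val": 0.55, "grain": 0.08}
_CLASS_CUES = (
    {"hue": 0.97, "sat": 0.30, "val": 0.70, "grain": 0.02},
    {"hue": 0.14, "sat": 0.85, "val": 0.60, "grain": 0.16},
)


def _blob_params(label: int, cue: float) -> dict[str, float]:
    target = _CLASS_CUES[label]
    return {k: _NEUTRAL[k] + cue * (target[k] - _NEUTRAL[k]) for k in _NEUTRAL}


def generate_images(spec: SyntheticSpec, n: int, seed: int | None = None):
    """Class-conditional synthetic images.

    Returns ``(images, y)`` with ``images`` of shape ``(n, S, S, 3)``,
    float values in ``[0, 1]``.  At ``cue_strength == 0`` the image
    distribution is identical for both classes, so no classifier can
    beat the majority prior in expectation.
    """
    if not spec.image_mode:
        raise ConfigurationError("spec is a feature spec; use generate_features")
    if n < 1:
        raise ConfigurationError("n must be >= 1")
    if spec.n_classes != 2:
        raise ConfigurationError("the image generator is binary")
    rng = np.random.default_rng(spec.seed if seed is None else seed)
    S = spec.image_size
    y = rng.choice(2, size=n, p=np.asarray(spec.class_priors))
    yy, xx = np.mgrid[0:S, 0:S].astype(np.float64)

    images = np.empty((n, S, S, 3), dtype=np.float64)
    for k in range(n):
        p = _blob_params(int(y[k]), spec.cue_strength)
        # skin-toned textured background
        bg_hsv = np.empty((S, S, 3))
        bg_hsv[..., 0] = 0.07 + rng.normal(0, 0.01)
        bg_hsv[..., 1] = 0.30 + rng.normal(0, 0.03)
        bg_hsv[..., 2] = np.clip(
            rng.uniform(0.55, 0.75) + 0.05 * rng.standard_normal((S, S)), 0, 1
        )
        bg = hsv_to_rgb(np.clip(bg_hsv, 0, 1))

        # soft-edged wound blob
        cy, cx = rng.uniform(0.35 * S, 0.65 * S, size=2)
        radius = rng.uniform(0.18, 0.32) * S
        dist = np.sqrt((yy - cy) ** 2 + (xx - cx) ** 2)
        mask = 1.0 / (1.0 + np.exp((dist - radius) / (0.05 * S)))

        blob_hsv = np.empty((S, S, 3))
        blob_hsv[..., 0] = (p["hue"] + rng.normal(0, 0.015)) % 1.0
        blob_hsv[..., 1] = p["sat"] + rng.normal(0, 0.04)
        blob_hsv[..., 2] = p["val"] + p["grain"] * rng.standard_normal((S, S))
        blob = hsv_to_rgb(np.clip(blob_hsv, 0, 1))

        images[k] = np.clip(bg * (1 - mask[..., None]) + blob * mask[..., None], 0, 1)
    return images, y


def write_image_dataset(spec: SyntheticSpec, n: int, out_dir, seed: int | None = None):
    """Generate images, write PNGs and a ``path,label`` manifest CSV.

    Paths in the manifest are relative to its directory.  Returns the
    manifest DataFrame; the manifest file itself is ``manifest.csv``
    inside ``out_dir``.
    """
    from pathlib import Path

    from PIL import Image

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    images, y = generate_images(spec, n, seed=seed)
    rows = []
    for k, (img, label) in enumerate(zip(images, y)):
        name = f"img_{k:05d}.png"
        Image.fromarray((img * 255).round().astype(np.uint8)).save(out_dir / name)
        rows.append({"path": name, "label": int(label)})
    manifest = pd.DataFrame(rows)
    manifest.to_csv(out_dir / "manifest.csv", index=False)
    return manifest


def images_to_batch(images: np.ndarray) -> np.ndarray:
    """``(B, S, S, 3)`` in ``[0, 1]`` to channel-first ``(B, 3, S, S)``."""
    return np.transpose(np.asarray(images, dtype=np.float64), (0, 3, 1, 2))
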