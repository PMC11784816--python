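"""Synthetic data with known ground truth for offline testing of the pipeline.

Two generators are provided:

* :func:`gen_features` — class-conditional Gaussian feature matrices with a
  known informative-feature subset, standing in for the deep-feature
  representation the selection stage consumes.  For each informative column
  the per-class means are drawn iid from ``N(0, (delta*sigma)^2 / 2)``, so
  the root-mean-square separation between any two class means is exactly
  ``delta * sigma``; the remaining columns are pure ``N(0, sigma^2)`` noise
  independent of the class label.

* :func:`gen_images` — small grayscale-motif PNG directories (disc, ring,
  cross, blank), one subdirectory per class, emulating the class-labeled
  image-folder layout of public MRI collections.  Motifs are linearly
  separable from raw pixels, so the full image pipeline has a known
  attainable accuracy.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
from PIL import Image

from .selection import FeatureMatrix

__all__ = ["FeatureGenSpec", "ImageGenSpec", "gen_features", "gen_images"]


@dataclass
class FeatureGenSpec:
    """Parameters of the Gaussian feature generator.

    ``delta`` is the class-mean separation in units of the noise standard
    deviation ``sigma``; ``k`` of the ``d`` columns carry class signal.
    """

    n: int = 600
    d: int = 64
    k: int = 8
    n_classes: int = 3
    delta: float = 2.0
    sigma: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not 1 <= self.k <= self.d:
            raise ValueError("require 1 <= k <= d")
        if self.n_classes < 2:
            raise ValueError("require at least 2 classes")
        if self.delta < 0:
            raise ValueError("delta must be >= 0")
        if self.sigma <= 0:
            raise ValueError("sigma must be > 0")
        if self.n < self.n_classes * 10:
            raise ValueError("require n >= 10 samples per class")


@dataclass
class ImageGenSpec:
    """Parameters of the geometric-motif image generator."""

    n_per_class: int = 20
    n_classes: int = 3
    size: int = 64
    noise: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_classes < 2 or self.n_classes > 4:
            raise ValueError("supported class counts: 2-4")
        if self.size < 32:
            raise ValueError("image size must be >= 32")
        if self.n_per_class < 1:
            raise ValueError("n_per_class must be >= 1")
        if not 0.0 <= self.noise <= 1.0:
            raise ValueError("noise must lie in [0, 1]")


def gen_features(spec: FeatureGenSpec) -> FeatureMatrix:
    """Generate a labeled feature matrix with a known informative subset."""
    rng = np.random.default_rng(spec.seed)
    n, d, k, C = spec.n, spec.d, spec.k, spec.n_classes

    # Balanced labels (counts within +-1 of n/C), order shuffled.
    labels = np.arange(n) % C
    rng.shuffle(labels)

    informative = np.zeros(d, dtype=bool)
    informative[rng.choice(d, size=k, replace=False)] = True

    # Per-class means for informative columns; RMS pairwise separation is
    # delta*sigma because Var(mu_a - mu_b) = (delta*sigma)^2.
    mu = rng.normal(0.0, spec.delta * spec.sigma / np.sqrt(2.0), size=(C, k))

    X = rng.normal(0.0, spec.sigma, size=(n, d))
    X[:, informative] += mu[labels]

    names = [f"f{i}" for i in range(d)]
    return FeatureMatrix(
        values=X,
        labels=labels.astype(np.int64),
        feature_names=names,
        informative_mask=informative,
    )


def _motif(name: str, size: int) -> np.ndarray:
    """Unit-intensity motif image in [0, 1], shape (size, size)."""
    yy, xx = np.mgrid[0:size, 0:size]
    cy = cx = (size - 1) / 2.0
    r = np.hypot(yy - cy, xx - cx)
    img = np.zeros((size, size))
    if name == "disc":
        img[r <= size * 0.25] = 1.0
    elif name == "ring":
        img[(r <= size * 0.35) & (r >= size * 0.22)] = 1.0
    elif name == "cross":
        w = max(2, size // 10)
        img[np.abs(yy - cy) <= w] = 1.0
        img[np.abs(xx - cx) <= w] = 1.0
    elif name == "blank":
        pass
    else:
        raise ValueError(f"unknown motif {name!r}")
    return img


MOTIF_ORDER = ["disc", "ring", "cross", "blank"]


def gen_images(spec: ImageGenSpec, out: str | Path) -> Path:
    """Write a class-labeled PNG directory of noisy geometric motifs.

    Returns the root path.  The directory layout (one subdirectory per
    class) is the one :func:`qgafs.features.load_image_directory` consumes.
    Byte-identical across runs with the same spec.
    """
    out = Path(out)
    rng = np.random.default_rng(spec.seed)
    classes = MOTIF_ORDER[: spec.n_classes]
    for cls in classes:
        cls_dir = out / cls
        cls_dir.mkdir(parents=True, exist_ok=True)
        base = _motif(cls, spec.size)
        for i in range(spec.n_per_class):
            noisy = base + rng.normal(0.0, spec.noise, size=base.shape)
            arr = np.clip(noisy, 0.0, 1.0)
            img = Image.fromarray((arr * 255).round().astype(np.uint8), mode="L")
            img.save(cls_dir / f"{cls}_{i:04d}.png")
    return out
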