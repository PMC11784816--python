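"""Image loading, preprocessing and pluggable deep-feature extraction.

The pipeline front end mirrors a standard transfer-learning setup: images
are resized to 128x128 RGB with pixel values in [0, 1], then mapped to a
fixed-length real feature vector by an object satisfying the
:class:`FeatureExtractor` contract.  The default extractor shipped here is
a seeded random projection of the flattened pixels followed by
rectification — a deterministic, dependency-free stand-in exposing the same
interface a pretrained convolutional backbone would.  Any callable with a
``dim`` attribute and per-image determinism can be plugged in instead.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Protocol, runtime_checkable

import numpy as np
from PIL import Image, UnidentifiedImageError

from .selection import FeatureMatrix

__all__ = [
    "ImageDataset",
    "FeatureExtractor",
    "RandomProjectionExtractor",
    "preprocess",
    "load_image_directory",
    "extract_features",
]

TARGET_SIZE = 128

_IMAGE_SUFFIXES = {".png", ".jpg", ".jpeg", ".bmp", ".tif", ".tiff"}


@dataclass
class ImageDataset:
    """Preprocessed images with integer class labels."""

    images: np.ndarray  # (n, H, W, 3), float in [0, 1]
    labels: np.ndarray  # (n,), int in 0..C-1
    class_names: list[str]
    paths: list[str] = field(default_factory=list)
    n_skipped: int = 0

    @property
    def n(self) -> int:
        return self.images.shape[0]

    @property
    def n_classes(self) -> int:
        return len(self.class_names)


def _resize_bilinear(channel: np.ndarray, size: int) -> np.ndarray:
    img = Image.fromarray(channel.astype(np.float32), mode="F")
    return np.asarray(img.resize((size, size), Image.BILINEAR), dtype=np.float64)


def preprocess(image: np.ndarray, size: int = TARGET_SIZE) -> np.ndarray:
    """Convert a raw image array to ``size x size x 3`` float in [0, 1].

    Integer inputs are divided by 255; grayscale inputs are replicated to 3
    channels; resizing is bilinear.  Idempotent: an already-conforming
    array passes through unchanged (up to copying).
    """
    arr = np.asarray(image)
    if arr.ndim == 3 and arr.shape[2] == 1:
        arr = arr[:, :, 0]
    if arr.ndim not in (2, 3):
        raise ValueError(f"expected a 2-D or 3-D image array, got shape {arr.shape}")
    if arr.ndim == 3 and arr.shape[2] != 3:
        raise ValueError(f"expected 3 channels, got {arr.shape[2]}")
    if arr.ndim == 2 and min(arr.shape) < 2 or arr.ndim == 3 and min(arr.shape[:2]) < 2:
        raise ValueError("image is too small to be meaningful")

    if np.issubdtype(arr.dtype, np.integer):
        arr = arr.astype(np.float64) / 255.0
    else:
        arr = arr.astype(np.float64)

    if arr.ndim == 2:
        arr = np.repeat(arr[:, :, None], 3, axis=2)

    if arr.shape[:2] != (size, size):
        arr = np.stack(
            [_resize_bilinear(arr[:, :, c], size) for c in range(3)], axis=2
        )
    return np.clip(arr, 0.0, 1.0)


def load_image_directory(root: str | Path, size: int = TARGET_SIZE) -> ImageDataset:
    """Load a class-labeled image directory (one subdirectory per class).

    Classes are ordered lexicographically by subdirectory name.  Unreadable
    files are skipped with a warning and counted in ``n_skipped``; a class
    with no readable image at all is an error.
    """
    root = Path(root)
    if not root.is_dir():
        raise FileNotFoundError(f"not a directory: {root}")
    class_dirs = sorted(p for p in root.iterdir() if p.is_dir())
    if not class_dirs:
        raise ValueError(f"no class subdirectories under {root}")

    images: list[np.ndarray] = []
    labels: list[int] = []
    paths: list[str] = []
    n_skipped = 0
    class_names = [p.name for p in class_dirs]
    for label, cls_dir in enumerate(class_dirs):
        files = sorted(
            p for p in cls_dir.iterdir() if p.suffix.lower() in _IMAGE_SUFFIXES
        )
        n_before = len(images)
        for f in files:
            try:
                with Image.open(f) as img:
                    arr = np.asarray(img.convert("RGB"))
            except (OSError, UnidentifiedImageError) as exc:
                warnings.warn(f"skipping unreadable image {f}: {exc}")
                n_skipped += 1
                continue
            images.append(preprocess(arr, size=size))
            labels.append(label)
            paths.append(str(f))
        if len(images) == n_before:
            raise ValueError(f"class {cls_dir.name!r} has no readable images")

    return ImageDataset(
        images=np.stack(images),
        labels=np.asarray(labels, dtype=np.int64),
        class_names=class_names,
        paths=paths,
        n_skipped=n_skipped,
    )


@runtime_checkable
class FeatureExtractor(Protocol):
    """Deterministic mapping from a preprocessed image to a length-d vector."""

    dim: int
    tag: str

    def __call__(self, image: np.ndarray) -> np.ndarray: ...


class RandomProjectionExtractor:
    """Seeded random projection of flattened pixels, rectified.

    ``f(x) = max(0, W @ flatten(x))`` with W drawn once from a seeded
    normal distribution scaled by 1/sqrt(n_pixels).  Deterministic given
    ``random_state``; linear up to the rectification, so classes separable
    in pixel space remain separable in feature space with high probability.
    """

    def __init__(
        self, dim: int = 64, input_size: int = TARGET_SIZE, random_state: int = 0
    ):
        if dim < 1:
            raise ValueError("dim must be >= 1")
        self.dim = dim
        self.input_size = input_size
        self.random_state = random_state
        rng = np.random.default_rng(random_state)
        n_in = input_size * input_size * 3
        self._weights = rng.normal(0.0, 1.0 / np.sqrt(n_in), size=(dim, n_in))
        self.tag = f"random-projection-d{dim}-seed{random_state}"

    def __call__(self, image: np.ndarray) -> np.ndarray:
        x = np.asarray(image, dtype=np.float64).ravel()
        if x.size != self._weights.shape[1]:
            raise ValueError(
                f"expected {self._weights.shape[1]} pixels, got {x.size}"
            )
        return np.maximum(0.0, self._weights @ x)


def extract_features(
    dataset: ImageDataset, extractor: FeatureExtractor
) -> FeatureMatrix:
    """Apply an extractor image-by-image; rows keep the dataset order."""
    if dataset.n == 0:
        raise ValueError("empty dataset")
    rows = []
    for img in dataset.images:
        vec = np.asarray(extractor(img), dtype=np.float64).ravel()
        if vec.shape[0] != extractor.dim:
            raise RuntimeError(
                f"extractor {extractor.tag!r} returned {vec.shape[0]} values, "
                f"declared dim {extractor.dim}"
            )
        rows.append(vec)
    values = np.stack(rows)
    names = [f"deep_{i}" for i in range(extractor.dim)]
    return FeatureMatrix(
        values=values, labels=dataset.labels.copy(), feature_names=names
    )
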