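"""Detector-image preprocessing for the classifier.

SANS intensities span decades, so the network input is the log-transformed,
max-normalised image x -> log(x + 1) / MaxLog, which maps raw counts into
[0, 1] independently of counting statistics, followed by a bilinear resize of
the 144 x 256 detector grid to the square 180 x 180 network input (180 is a
compromise between the two detector dimensions: one axis is upsampled, the
other downsampled). Preprocessing is applied on the fly; raw counts stay the
dataset of record.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from skimage.transform import resize as _sk_resize

from .exceptions import ValidationError

__all__ = ["PreprocessedImage", "log_normalize", "resize", "preprocess", "preprocess_stack"]

TARGET_SHAPE = (180, 180)


@dataclass(frozen=True)
class PreprocessedImage:
    """180 x 180 network input in [0, 1] plus the normalising constant."""

    values: np.ndarray
    max_log: float


def log_normalize(image) -> tuple[np.ndarray, float]:
    """Per-pixel log(x + 1) divided by the post-log maximum; returns (grid, MaxLog).

    The base of the logarithm cancels in the ratio. Negative pixels are a
    contract violation; an all-zero image has MaxLog = 0 and must have been
    removed by cleaning, so it raises.
    """
    arr = np.asarray(image, dtype=np.float64)
    if np.any(arr < 0):
        raise ValidationError("image contains negative pixel values")
    logged = np.log1p(arr)
    max_log = float(logged.max()) if logged.size else 0.0
    if max_log == 0.0:
        raise ValidationError("all-zero image: MaxLog = 0 (clean the dataset first)")
    return logged / max_log, max_log


def resize(grid, shape: tuple[int, int] = TARGET_SHAPE) -> np.ndarray:
    """Bilinear resize (half-pixel-centred coordinates), clamped to [0, 1]."""
    out = _sk_resize(
        np.asarray(grid, dtype=np.float64),
        shape,
        order=1,
        mode="edge",
        anti_aliasing=False,
        preserve_range=True,
    )
    return np.clip(out, 0.0, 1.0)


def preprocess(image) -> PreprocessedImage:
    """log-normalise then resize one raw 144 x 256 count image."""
    grid, max_log = log_normalize(image)
    return PreprocessedImage(values=resize(grid), max_log=max_log)


def preprocess_stack(images) -> np.ndarray:
    """Preprocess an (n, 144, 256) stack into an (n, 180, 180) float32 array."""
    images = np.asarray(images)
    out = np.empty((len(images), *TARGET_SHAPE), dtype=np.float32)
    for i, img in enumerate(images):
        out[i] = preprocess(img).values
    return out
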