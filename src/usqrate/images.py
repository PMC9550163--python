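"""Grayscale image container and I/O helpers.

Every pixel field in this package is a 2-D float64 array with intensities
in [0, 1]. :func:`as_gray` is the single entry point that coerces and
validates arbitrary input (uint8 images, colour images, float arrays) into
that canonical form.
"""

from __future__ import annotations

import os
from typing import Iterable

import numpy as np

__all__ = ["as_gray", "validate_gray", "load_image", "save_image", "min_size_for_steps"]


def validate_gray(pixels: np.ndarray) -> np.ndarray:
    """Validate a canonical grayscale image (2-D float in [0, 1])."""
    arr = np.asarray(pixels)
    if arr.ndim != 2:
        raise ValueError(f"expected a 2-D grayscale image, got shape {arr.shape}")
    if arr.size == 0:
        raise ValueError("empty image")
    if not np.issubdtype(arr.dtype, np.floating):
        raise ValueError(f"expected float pixels, got dtype {arr.dtype}")
    if not np.isfinite(arr).all():
        raise ValueError("image contains non-finite pixels")
    lo, hi = float(arr.min()), float(arr.max())
    if lo < 0.0 or hi > 1.0:
        raise ValueError(f"pixel values outside [0, 1]: min={lo:g}, max={hi:g}")
    return np.ascontiguousarray(arr, dtype=np.float64)


def as_gray(data: np.ndarray) -> np.ndarray:
    """Coerce an array-like image into canonical 2-D float64 in [0, 1].

    Integer images are rescaled by their dtype maximum; RGB(A) images are
    converted with the ITU-R 601 luma weights.
    """
    arr = np.asarray(data)
    if arr.ndim == 3:
        if arr.shape[-1] not in (3, 4):
            raise ValueError(f"cannot interpret shape {arr.shape} as an image")
        rgb = arr[..., :3].astype(np.float64)
        arr = rgb @ np.array([0.299, 0.587, 0.114])
    if np.issubdtype(arr.dtype, np.integer):
        info = np.iinfo(arr.dtype) if arr.dtype != np.int64 else np.iinfo(np.int64)
        arr = arr.astype(np.float64) / float(max(info.max, 1))
    arr = np.asarray(arr, dtype=np.float64)
    # tolerate tiny numeric overshoot from conversions
    arr = np.clip(arr, 0.0, 1.0)
    return validate_gray(arr)


def load_image(path: str | os.PathLike) -> np.ndarray:
    """Read a PNG/TIFF/JPEG file as a canonical grayscale image."""
    import imageio.v3 as iio

    return as_gray(iio.imread(path))


def save_image(path: str | os.PathLike, pixels: np.ndarray) -> None:
    """Write a canonical grayscale image as 8-bit PNG/TIFF."""
    import imageio.v3 as iio

    arr = validate_gray(pixels)
    iio.imwrite(path, np.round(arr * 255).astype(np.uint8))


def min_size_for_steps(steps: int) -> int:
    """Smallest image side that admits the largest kernel of a *steps*-step sweep."""
    return 2 * (steps + 1) - 1


def check_same_shape(a: np.ndarray, b: np.ndarray) -> None:
    if a.shape != b.shape:
        raise ValueError(f"image shape mismatch: {a.shape} vs {b.shape}")


def iter_validated(images: Iterable[np.ndarray]) -> Iterable[np.ndarray]:
    for im in images:
        yield validate_gray(np.asarray(im, dtype=np.float64))
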