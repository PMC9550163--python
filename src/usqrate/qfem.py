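"""Quantitative Feature Extraction Machine (QFEM).

An input image X is filtered at a sequence of growing odd kernel sizes
n = 2N-1 for N = 2 .. steps+1 (3, 5, 7, ... at the default eight steps up
to 17). After each step the 15 full-reference quality metrics are computed
with the unfiltered input X as reference and the filtered image Y_n as
test, and the per-step vectors are concatenated into one feature vector of
length steps*15 (120 at the default steps=8).

The working intuition: filtering progressively removes the degradation
signature (speckle, noise, blur artefacts), and how quickly and in what
pattern the quality metrics change across kernel scales is characteristic
of the degradation class.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Literal, Sequence

import numpy as np
import pandas as pd
from scipy import ndimage

from .images import min_size_for_steps, validate_gray
from .metrics import METRIC_NAMES, N_METRICS, compute_metrics

__all__ = [
    "FilterKind",
    "FilterSpec",
    "QfemFeatures",
    "apply_filter",
    "kernel_sequence",
    "extract",
    "extract_batch",
    "feature_names",
]

logger = logging.getLogger(__name__)

FilterKind = Literal["median", "average", "gaussian", "bilateral"]
FILTER_KINDS: tuple[str, ...] = ("median", "average", "gaussian", "bilateral")


@dataclass(frozen=True)
class FilterSpec:
    """A single smoothing-filter configuration.

    Parameters
    ----------
    kind
        One of ``median``, ``average``, ``gaussian``, ``bilateral``.
    kernel
        Odd window size >= 3.
    sigma
        Gaussian standard deviation; defaults to kernel/6 so the window
        spans +/- 3 sigma.
    sigma_space, sigma_intensity
        Bilateral range/space bandwidths; defaults kernel/6 and 0.1.
    """

    kind: str
    kernel: int
    sigma: float | None = None
    sigma_space: float | None = None
    sigma_intensity: float = 0.1

    def __post_init__(self) -> None:
        if self.kind not in FILTER_KINDS:
            raise ValueError(f"unknown filter kind {self.kind!r}; expected one of {FILTER_KINDS}")
        if self.kernel < 3 or self.kernel % 2 == 0:
            raise ValueError(f"kernel must be an odd integer >= 3, got {self.kernel}")
        if self.kind == "gaussian" and self.sigma is not None and self.sigma <= 0:
            raise ValueError("gaussian sigma must be positive")
        if self.kind == "bilateral":
            if self.sigma_space is not None and self.sigma_space <= 0:
                raise ValueError("bilateral sigma_space must be positive")
            if self.sigma_intensity <= 0:
                raise ValueError("bilateral sigma_intensity must be positive")

    @property
    def effective_sigma(self) -> float:
        return self.sigma if self.sigma is not None else self.kernel / 6.0

    @property
    def effective_sigma_space(self) -> float:
        return self.sigma_space if self.sigma_space is not None else self.kernel / 6.0


@dataclass(frozen=True)
class QfemFeatures:
    """Concatenated per-step metric vectors for one image."""

    values: np.ndarray
    steps: int
    kernel_sequence: tuple[int, ...]
    filter_kind: str = "median"
    names: tuple[str, ...] = field(default=(), compare=False)

    def __post_init__(self) -> None:
        vals = np.asarray(self.values, dtype=np.float64)
        if vals.ndim != 1 or vals.size != self.steps * N_METRICS:
            raise ValueError(
                f"feature vector length {vals.size} != steps*{N_METRICS} = {self.steps * N_METRICS}"
            )
        expected = kernel_sequence(self.steps)
        if tuple(self.kernel_sequence) != expected:
            raise ValueError(f"kernel_sequence {self.kernel_sequence} != {expected}")
        object.__setattr__(self, "values", vals)
        if not self.names:
            object.__setattr__(self, "names", tuple(feature_names(self.steps)))

    def __len__(self) -> int:
        return self.values.size


def kernel_sequence(steps: int) -> tuple[int, ...]:
    """Odd kernels n = 2N-1 for N = 2 .. steps+1."""
    if steps < 1:
        raise ValueError("steps must be >= 1")
    return tuple(2 * n - 1 for n in range(2, steps + 2))


def feature_names(steps: int) -> list[str]:
    """Column labels ``k{kernel}_{METRIC}`` matching the feature order."""
    return [f"k{k}_{m}" for k in kernel_sequence(steps) for m in METRIC_NAMES]


def apply_filter(image: np.ndarray, spec: FilterSpec) -> np.ndarray:
    """Smooth an image with the given filter; reflect border handling.

    The output has the input's shape and stays in [0, 1].
    """
    img = validate_gray(image)
    if spec.kernel > min(img.shape):
        raise ValueError(
            f"kernel {spec.kernel} exceeds image dimensions {img.shape}"
        )
    if spec.kind == "median":
        out = ndimage.median_filter(img, size=spec.kernel, mode="reflect")
    elif spec.kind == "average":
        out = ndimage.uniform_filter(img, size=spec.kernel, mode="reflect")
    elif spec.kind == "gaussian":
        sigma = spec.effective_sigma
        radius = (spec.kernel - 1) // 2
        out = ndimage.gaussian_filter(img, sigma=sigma, mode="reflect", radius=radius)
    else:  # bilateral
        from skimage.restoration import denoise_bilateral

        out = denoise_bilateral(
            img,
            win_size=spec.kernel,
            sigma_color=spec.sigma_intensity,
            sigma_spatial=spec.effective_sigma_space,
            mode="reflect",
        )
    return np.clip(out, 0.0, 1.0)


def extract(image: np.ndarray, steps: int = 8, filter_kind: str = "median") -> QfemFeatures:
    """Run the multi-step filter sweep on one image.

    For each step the image is filtered at the next odd kernel and the 15
    quality metrics are computed between the original (reference) and the
    filtered image (test); the metric vectors are concatenated in step order.

    Raises
    ------
    ValueError
        If the image is too small for the largest kernel of the sweep.
    """
    img = validate_gray(image)
    kernels = kernel_sequence(steps)
    need = min_size_for_steps(steps)
    if min(img.shape) < need:
        raise ValueError(
            f"image {img.shape} too small for {steps}-step sweep "
            f"(largest kernel {kernels[-1]} needs side >= {need})"
        )
    blocks = []
    for k in kernels:
        filtered = apply_filter(img, FilterSpec(kind=filter_kind, kernel=k))
        blocks.append(compute_metrics(img, filtered))
    return QfemFeatures(
        values=np.concatenate(blocks),
        steps=steps,
        kernel_sequence=kernels,
        filter_kind=filter_kind,
    )


def extract_batch(
    images: Iterable[np.ndarray],
    labels: Sequence[str] | None = None,
    steps: int = 8,
    filter_kind: str = "median",
    ids: Sequence[str] | None = None,
    strict: bool = True,
) -> pd.DataFrame:
    """Extract features for a collection of images into a tidy table.

    One row per image, columns named ``k{kernel}_{METRIC}``, with ``label``
    and ``image_id`` carried through in input order. In non-strict mode a
    failing image is logged with its identifier and skipped; in strict mode
    the failure aborts the batch.
    """
    images = list(images)
    if not images:
        raise ValueError("empty image collection")
    if labels is not None and len(labels) != len(images):
        raise ValueError("labels length does not match images")
    if ids is None:
        ids = [f"img{i:05d}" for i in range(len(images))]
    rows, kept = [], []
    for i, img in enumerate(images):
        try:
            rows.append(extract(img, steps=steps, filter_kind=filter_kind).values)
            kept.append(i)
        except ValueError as err:
            if strict:
                raise ValueError(f"feature extraction failed for {ids[i]}: {err}") from err
            logger.warning("skipping %s: %s", ids[i], err)
    table = pd.DataFrame(np.vstack(rows), columns=feature_names(steps))
    table.insert(0, "image_id", [ids[i] for i in kept])
    if labels is not None:
        table.insert(1, "label", [labels[i] for i in kept])
    return table
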