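"""Synthetic ultrasound-like dataset generator.

Produces the four quality classes a rating model must separate — normal,
noisy, blurry, distorted — from independently drawn clean bases, standing
in for a clinical collection that is not publicly available.

A clean base emulates a B-mode scan: a smooth anatomical intensity field
(low-pass-filtered Gaussian random field) with one to three elliptic
"lesion" regions of shifted mean intensity, multiplied by mild
mean-normalised Rayleigh speckle (the granular interference pattern
intrinsic to coherent imaging), clipped to [0, 1]. Degradations:

normal
    identity — the clean base itself.
noisy
    strong multiplicative speckle plus additive Gaussian noise.
blurry
    Gaussian blur.
distorted
    smooth random geometric warp plus contrast crush and intensity banding.

Each image draws its own clean base and its own degradation parameters, so
a classifier must key on quality signatures rather than image content.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage

__all__ = ["CLASS_NAMES", "SynthConfig", "make_clean", "degrade", "build_dataset"]

CLASS_NAMES: tuple[str, ...] = ("normal", "noisy", "blurry", "distorted")


@dataclass(frozen=True)
class SynthConfig:
    """Generator settings; defaults give classes that are separable but
    overlapping at the boundaries.

    noise_sigma_range : additive Gaussian sigma for the noisy class
    blur_sigma_range : Gaussian blur sigma for the blurry class
    distortion_strength_range : warp amplitude in pixels for the distorted class
    speckle_scale : mixing strength of the mild speckle on clean bases, in [0, 1]
    """

    n_per_class: int = 650
    image_size: tuple[int, int] = (64, 64)
    seed: int = 0
    noise_sigma_range: tuple[float, float] = (0.05, 0.2)
    blur_sigma_range: tuple[float, float] = (1.5, 4.0)
    distortion_strength_range: tuple[float, float] = (2.0, 6.0)
    speckle_scale: float = 0.3

    def __post_init__(self) -> None:
        if self.n_per_class < 1:
            raise ValueError("n_per_class must be >= 1")
        if min(self.image_size) < 17:
            raise ValueError("image_size must be at least 17 on each side (8-step kernel fit)")
        for name in ("noise_sigma_range", "blur_sigma_range", "distortion_strength_range"):
            lo, hi = getattr(self, name)
            if not (0 < lo <= hi):
                raise ValueError(f"{name} must be a nonempty positive interval")
        if not (0 < self.speckle_scale <= 1):
            raise ValueError("speckle_scale must lie in (0, 1]")


def _rayleigh_speckle(shape: tuple[int, int], strength: float, rng: np.random.Generator) -> np.ndarray:
    """Mean-one multiplicative speckle field: 1 + strength*(R/E[R] - 1)."""
    r = rng.rayleigh(scale=1.0, size=shape)
    r /= np.sqrt(np.pi / 2.0)  # Rayleigh(1) mean
    return 1.0 + strength * (r - 1.0)


def make_clean(config: SynthConfig, rng: np.random.Generator) -> np.ndarray:
    """Draw one clean ultrasound-like base image."""
    h, w = config.image_size
    base = rng.normal(size=(h, w))
    base = ndimage.gaussian_filter(base, sigma=min(h, w) / 10.0, mode="reflect")
    lo, hi = base.min(), base.max()
    base = 0.25 + 0.45 * (base - lo) / max(hi - lo, 1e-12)

    yy, xx = np.mgrid[0:h, 0:w]
    for _ in range(rng.integers(1, 4)):
        cy, cx = rng.uniform(0.2, 0.8) * h, rng.uniform(0.2, 0.8) * w
        ay, ax = rng.uniform(0.08, 0.25) * h, rng.uniform(0.08, 0.25) * w
        theta = rng.uniform(0, np.pi)
        dy, dx = yy - cy, xx - cx
        ry = dy * np.cos(theta) + dx * np.sin(theta)
        rx = -dy * np.sin(theta) + dx * np.cos(theta)
        inside = (ry / ay) ** 2 + (rx / ax) ** 2 <= 1.0
        base = np.where(inside, base + rng.uniform(-0.25, 0.3), base)

    img = base * _rayleigh_speckle((h, w), config.speckle_scale, rng)
    return np.clip(img, 0.0, 1.0)


def degrade(
    image: np.ndarray,
    label: str,
    config: SynthConfig,
    rng: np.random.Generator,
) -> tuple[np.ndarray, dict[str, float]]:
    """Apply a class-specific degradation; returns the image and the drawn
    parameters (for the manifest). ``normal`` is the identity."""
    img = np.asarray(image, dtype=np.float64)
    params: dict[str, float] = {}
    if label == "normal":
        out = img.copy()
    elif label == "noisy":
        sigma = rng.uniform(*config.noise_sigma_range)
        params["noise_sigma"] = sigma
        out = img * _rayleigh_speckle(img.shape, 1.0, rng) + rng.normal(0.0, sigma, size=img.shape)
    elif label == "blurry":
        sigma = rng.uniform(*config.blur_sigma_range)
        params["blur_sigma"] = sigma
        out = ndimage.gaussian_filter(img, sigma=sigma, mode="reflect")
    elif label == "distorted":
        amp = rng.uniform(*config.distortion_strength_range)
        params["warp_amplitude"] = amp
        h, w = img.shape
        dy = ndimage.gaussian_filter(rng.normal(size=(h, w)), sigma=min(h, w) / 8.0, mode="reflect")
        dx = ndimage.gaussian_filter(rng.normal(size=(h, w)), sigma=min(h, w) / 8.0, mode="reflect")
        for d in (dy, dx):
            peak = np.abs(d).max()
            d *= amp / max(peak, 1e-12)
        yy, xx = np.mgrid[0:h, 0:w].astype(np.float64)
        out = ndimage.map_coordinates(img, [yy + dy, xx + dx], order=1, mode="reflect")
        # contrast crush and intensity banding
        crush = rng.uniform(0.4, 0.6)
        params["contrast_crush"] = crush
        out = 0.5 + crush * (out - 0.5)
        levels = int(rng.integers(5, 9))
        params["banding_levels"] = levels
        out = np.round(out * (levels - 1)) / (levels - 1)
    else:
        raise ValueError(f"unknown label {label!r}; expected one of {CLASS_NAMES}")
    return np.clip(out, 0.0, 1.0), params


def build_dataset(config: SynthConfig) -> tuple[list[np.ndarray], list[str], pd.DataFrame]:
    """Generate a class-balanced labelled collection plus a manifest.

    The manifest records, per image, its identifier, label, the per-image
    child-seed and the drawn degradation parameters. Identical configs
    yield identical images and manifests.
    """
    images: list[np.ndarray] = []
    labels: list[str] = []
    records: list[dict] = []
    root = np.random.SeedSequence(config.seed)
    children = root.spawn(4 * config.n_per_class)
    k = 0
    for label in CLASS_NAMES:
        for i in range(config.n_per_class):
            child = children[k]
            rng = np.random.default_rng(child)
            clean = make_clean(config, rng)
            img, params = degrade(clean, label, config, rng)
            image_id = f"{label}_{i:04d}"
            images.append(img)
            labels.append(label)
            rec = {"image_id": image_id, "label": label, "seed_entropy": str(child.entropy), "spawn_key": k}
            rec.update(params)
            records.append(rec)
            k += 1
    manifest = pd.DataFrame(records)
    return images, labels, manifest
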