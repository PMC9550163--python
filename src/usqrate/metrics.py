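"""Full-reference image quality metrics.

Fifteen scalar metrics computed between a reference image X and a test
image Y, the per-step feature set of the multi-scale extractor. The roster
is the canonical full-reference set of the despeckling / IQA literature:

====  ============  =====================================================
 #    name          definition (X reference, Y test, n pixels)
====  ============  =====================================================
 0    MSE           mean((X-Y)^2)
 1    RMSE          sqrt(MSE)
 2    PSNR          10*log10(1/MSE), capped at 100 dB
 3    SNR           10*log10(sum(X^2)/sum((X-Y)^2)), clipped to +/-100 dB
 4    MAE           mean(|X-Y|)
 5    SSIM          mean local structural similarity (Gaussian window)
 6    UQI           universal quality index (global Wang-Bovik Q)
 7    NCC           sum(X*Y)/sum(X^2)
 8    AD            mean(X-Y)  (average difference)
 9    SC            sum(X^2)/sum(Y^2)  (structural content)
10    MD            max(|X-Y|)
11    NAE           sum(|X-Y|)/sum(|X|)
12    LMSE          sum((L(X)-L(Y))^2)/sum(L(X)^2), L = 3x3 Laplacian
13    EPI           corr(L(X)-mean, L(Y)-mean)  (edge preservation)
14    ENTROPY_DIFF  H(X)-H(Y), Shannon entropy over 256 bins on [0,1]
====  ============  =====================================================

All arithmetic is double precision. Degenerate denominators never produce
infinities: ratio metrics return their identical-image value when both
numerator and denominator vanish, and are capped otherwise (see
:data:`RATIO_CAP`), so a metric vector is always finite and usable as
classifier input.
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage

from .images import check_same_shape, validate_gray

__all__ = [
    "METRIC_NAMES",
    "N_METRICS",
    "compute_metrics",
    "metrics_dict",
    "ssim",
]

METRIC_NAMES: tuple[str, ...] = (
    "MSE",
    "RMSE",
    "PSNR",
    "SNR",
    "MAE",
    "SSIM",
    "UQI",
    "NCC",
    "AD",
    "SC",
    "MD",
    "NAE",
    "LMSE",
    "EPI",
    "ENTROPY_DIFF",
)
N_METRICS = len(METRIC_NAMES)

#: dB ceiling for PSNR/SNR on (near-)identical images.
DB_CAP = 100.0
#: cap for ratio metrics whose denominator vanishes while the numerator does not.
RATIO_CAP = 1e6

LAPLACIAN_KERNEL = np.array([[0.0, 1.0, 0.0], [1.0, -4.0, 1.0], [0.0, 1.0, 0.0]])

# standard published SSIM parameterisation
_SSIM_WIN = 11
_SSIM_SIGMA = 1.5
_SSIM_C1 = 0.01**2
_SSIM_C2 = 0.03**2


def _safe_ratio(num: float, den: float, identity: float) -> float:
    """num/den with degenerate denominators mapped to finite values."""
    if den == 0.0:
        if num == 0.0:
            return identity
        return float(np.sign(num)) * RATIO_CAP
    return float(np.clip(num / den, -RATIO_CAP, RATIO_CAP))


def _gaussian_window(size: int, sigma: float) -> np.ndarray:
    r = (size - 1) // 2
    x = np.arange(-r, r + 1, dtype=np.float64)
    g = np.exp(-0.5 * (x / sigma) ** 2)
    w = np.outer(g, g)
    return w / w.sum()


def ssim(x: np.ndarray, y: np.ndarray, win_size: int = _SSIM_WIN, sigma: float = _SSIM_SIGMA) -> float:
    """Mean structural similarity over the valid local-window map.

    Uses an 11x11 Gaussian window (sigma 1.5) and the standard stability
    constants c1=0.01^2, c2=0.03^2 for a unit data range. For images smaller
    than the window, the window shrinks to the largest odd size that fits.
    """
    h, w = x.shape
    win = min(win_size, h if h % 2 else h - 1, w if w % 2 else w - 1)
    if win < 1:
        raise ValueError("image too small for SSIM")
    kern = _gaussian_window(win, sigma)

    from numpy.lib.stride_tricks import sliding_window_view

    wx = sliding_window_view(x, (win, win))
    wy = sliding_window_view(y, (win, win))
    mu_x = np.einsum("ijkl,kl->ij", wx, kern)
    mu_y = np.einsum("ijkl,kl->ij", wy, kern)
    xx = np.einsum("ijkl,kl->ij", wx * wx, kern)
    yy = np.einsum("ijkl,kl->ij", wy * wy, kern)
    xy = np.einsum("ijkl,kl->ij", wx * wy, kern)
    var_x = xx - mu_x**2
    var_y = yy - mu_y**2
    cov = xy - mu_x * mu_y
    num = (2 * mu_x * mu_y + _SSIM_C1) * (2 * cov + _SSIM_C2)
    den = (mu_x**2 + mu_y**2 + _SSIM_C1) * (var_x + var_y + _SSIM_C2)
    return float(np.mean(num / den))


def _entropy(x: np.ndarray) -> float:
    hist, _ = np.histogram(x, bins=256, range=(0.0, 1.0))
    p = hist / hist.sum()
    nz = p[p > 0]
    return float(-(nz * np.log2(nz)).sum())


def _laplacian(x: np.ndarray) -> np.ndarray:
    return ndimage.correlate(x, LAPLACIAN_KERNEL, mode="reflect")


def compute_metrics(reference: np.ndarray, test: np.ndarray) -> np.ndarray:
    """Compute the 15 metrics between a reference and a test image.

    Parameters
    ----------
    reference, test
        2-D float arrays in [0, 1] of identical shape.

    Returns
    -------
    numpy.ndarray
        Length-15 float64 vector ordered as :data:`METRIC_NAMES`.
    """
    x = validate_gray(reference)
    y = validate_gray(test)
    check_same_shape(x, y)

    diff = x - y
    mse = float(np.mean(diff**2))
    rmse = float(np.sqrt(mse))
    psnr = DB_CAP if mse == 0.0 else min(10.0 * np.log10(1.0 / mse), DB_CAP)

    sig = float(np.sum(x**2))
    noise = float(np.sum(diff**2))
    if noise == 0.0:
        snr = DB_CAP
    elif sig == 0.0:
        snr = -DB_CAP
    else:
        snr = float(np.clip(10.0 * np.log10(sig / noise), -DB_CAP, DB_CAP))

    mae = float(np.mean(np.abs(diff)))
    md = float(np.max(np.abs(diff)))
    ad = float(np.mean(diff))
    nae = _safe_ratio(float(np.sum(np.abs(diff))), float(np.sum(np.abs(x))), 0.0)
    sc = _safe_ratio(sig, float(np.sum(y**2)), 1.0)
    ncc = _safe_ratio(float(np.sum(x * y)), sig, 1.0)

    mx, my = float(x.mean()), float(y.mean())
    vx, vy = float(x.var()), float(y.var())
    cov = float(((x - mx) * (y - my)).mean())
    uqi = _safe_ratio(4.0 * cov * mx * my, (vx + vy) * (mx**2 + my**2), 1.0 if np.array_equal(x, y) else 0.0)

    lx, ly = _laplacian(x), _laplacian(y)
    lmse = _safe_ratio(float(np.sum((lx - ly) ** 2)), float(np.sum(lx**2)), 0.0)
    dlx = lx - lx.mean()
    dly = ly - ly.mean()
    epi_den = float(np.sqrt(np.sum(dlx**2) * np.sum(dly**2)))
    epi_num = float(np.sum(dlx * dly))
    epi = _safe_ratio(epi_num, epi_den, 1.0 if np.array_equal(x, y) else 0.0)

    values = np.array(
        [
            mse,
            rmse,
            psnr,
            snr,
            mae,
            ssim(x, y),
            uqi,
            ncc,
            ad,
            sc,
            md,
            nae,
            lmse,
            epi,
            _entropy(x) - _entropy(y),
        ],
        dtype=np.float64,
    )
    assert np.isfinite(values).all()
    return values


def metrics_dict(reference: np.ndarray, test: np.ndarray) -> dict[str, float]:
    """Same as :func:`compute_metrics` but keyed by metric name."""
    return dict(zip(METRIC_NAMES, compute_metrics(reference, test)))
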