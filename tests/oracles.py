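"""Independent brute-force oracles used by the tests.

Everything here is written straight from the defining formulas with
explicit Python loops, deliberately sharing no code with the package.
"""

from __future__ import annotations

import math

import numpy as np


def naive_metrics(x: np.ndarray, y: np.ndarray) -> dict[str, float]:
    """The 15 full-reference metrics computed with per-pixel loops."""
    h, w = x.shape
    n = h * w
    se = ae = d_sum = 0.0
    sig = sig_y = xy = 0.0
    absx = 0.0
    md = 0.0
    for i in range(h):
        for j in range(w):
            d = x[i, j] - y[i, j]
            se += d * d
            ae += abs(d)
            d_sum += d
            sig += x[i, j] ** 2
            sig_y += y[i, j] ** 2
            xy += x[i, j] * y[i, j]
            absx += abs(x[i, j])
            md = max(md, abs(d))
    mse = se / n
    rmse = math.sqrt(mse)
    psnr = 100.0 if mse == 0 else min(10 * math.log10(1.0 / mse), 100.0)
    if se == 0:
        snr = 100.0
    elif sig == 0:
        snr = -100.0
    else:
        snr = min(max(10 * math.log10(sig / se), -100.0), 100.0)
    mae = ae / n
    ad = d_sum / n
    nae = ae / absx if absx > 0 else 0.0
    sc = sig / sig_y if sig_y > 0 else (1.0 if sig == 0 else 1e6)
    ncc = xy / sig if sig > 0 else (1.0 if xy == 0 else 1e6)

    mx = sum(x.ravel()) / n
    my = sum(y.ravel()) / n
    vx = sum((v - mx) ** 2 for v in x.ravel()) / n
    vy = sum((v - my) ** 2 for v in y.ravel()) / n
    cov = sum((a - mx) * (b - my) for a, b in zip(x.ravel(), y.ravel())) / n
    den = (vx + vy) * (mx**2 + my**2)
    uqi = 4 * cov * mx * my / den if den > 0 else (1.0 if np.array_equal(x, y) else 0.0)

    lx = naive_laplacian(x)
    ly = naive_laplacian(y)
    lnum = sum((a - b) ** 2 for a, b in zip(lx.ravel(), ly.ravel()))
    lden = sum(a * a for a in lx.ravel())
    lmse = lnum / lden if lden > 0 else 0.0
    mlx = lx.mean()
    mly = ly.mean()
    dlx = lx - mlx
    dly = ly - mly
    eden = math.sqrt((dlx**2).sum() * (dly**2).sum())
    epi = float((dlx * dly).sum() / eden) if eden > 0 else (1.0 if np.array_equal(x, y) else 0.0)

    return {
        "MSE": mse,
        "RMSE": rmse,
        "PSNR": psnr,
        "SNR": snr,
        "MAE": mae,
        "SSIM": naive_ssim(x, y),
        "UQI": uqi,
        "NCC": ncc,
        "AD": ad,
        "SC": sc,
        "MD": md,
        "NAE": nae,
        "LMSE": lmse,
        "EPI": epi,
        "ENTROPY_DIFF": naive_entropy(x) - naive_entropy(y),
    }


def naive_laplacian(x: np.ndarray) -> np.ndarray:
    """3x3 Laplacian [[0,1,0],[1,-4,1],[0,1,0]] with reflect padding, by loops."""
    h, w = x.shape

    def px(i: int, j: int) -> float:
        # scipy 'reflect' mode: (d c b a | a b c d | d c b a)
        if i < 0:
            i = -i - 1
        if i >= h:
            i = 2 * h - i - 1
        if j < 0:
            j = -j - 1
        if j >= w:
            j = 2 * w - j - 1
        return x[i, j]

    out = np.zeros_like(x)
    for i in range(h):
        for j in range(w):
            out[i, j] = px(i - 1, j) + px(i + 1, j) + px(i, j - 1) + px(i, j + 1) - 4 * x[i, j]
    return out


def naive_ssim(x: np.ndarray, y: np.ndarray, win: int = 11, sigma: float = 1.5) -> float:
    """Mean SSIM over all fully-contained windows, Gaussian-weighted stats."""
    h, w = x.shape
    win = min(win, h if h % 2 else h - 1, w if w % 2 else w - 1)
    r = (win - 1) // 2
    g = np.array([math.exp(-0.5 * (k / sigma) ** 2) for k in range(-r, r + 1)])
    kern = np.outer(g, g)
    kern /= kern.sum()
    c1, c2 = 0.01**2, 0.03**2
    vals = []
    for i in range(r, h - r):
        for j in range(r, w - r):
            wx = x[i - r : i + r + 1, j - r : j + r + 1]
            wy = y[i - r : i + r + 1, j - r : j + r + 1]
            mx = (kern * wx).sum()
            my = (kern * wy).sum()
            vx = (kern * wx * wx).sum() - mx * mx
            vy = (kern * wy * wy).sum() - my * my
            cov = (kern * wx * wy).sum() - mx * my
            vals.append(
                ((2 * mx * my + c1) * (2 * cov + c2))
                / ((mx * mx + my * my + c1) * (vx + vy + c2))
            )
    return float(np.mean(vals))


def naive_entropy(x: np.ndarray) -> float:
    counts = [0] * 256
    for v in x.ravel():
        b = min(int(v * 256), 255)
        counts[b] += 1
    n = x.size
    h = 0.0
    for c in counts:
        if c:
            p = c / n
            h -= p * math.log2(p)
    return h


def naive_median_filter(x: np.ndarray, k: int) -> np.ndarray:
    """Interior-only sliding-window sort median; border left as input."""
    h, w = x.shape
    r = (k - 1) // 2
    out = x.copy()
    for i in range(r, h - r):
        for j in range(r, w - r):
            window = sorted(x[i - r : i + r + 1, j - r : j + r + 1].ravel().tolist())
            out[i, j] = window[len(window) // 2]
    return out


def naive_fuzzy_forward(fmap: np.ndarray, p: float, q: float, r: float, sigma: float) -> np.ndarray:
    """Per-channel, per-membership-function loops with exact-tie MOM."""

    def g(v):
        return math.exp(-((v - q) ** 2) / (2 * sigma**2))

    def tri(v):
        if v <= p or v >= r:
            return 0.0
        if v <= q:
            return (v - p) / (q - p)
        return (r - v) / (r - q)

    def s(v):
        m = 0.5 * (p + r)
        if v <= p:
            return 0.0
        if v <= m:
            return 2 * ((v - p) / (r - p)) ** 2
        if v <= r:
            return 1 - 2 * ((v - r) / (r - p)) ** 2
        return 1.0

    h, w, c = fmap.shape
    out = []
    for fn in (g, tri, s):
        for ch in range(c):
            degrees = [[fn(fmap[i, j, ch]) for j in range(w)] for i in range(h)]
            top = max(max(row) for row in degrees)
            tol = 1e-6 * max(abs(top), 1e-300)
            vals = [
                fmap[i, j, ch]
                for i in range(h)
                for j in range(w)
                if degrees[i][j] >= top - tol
            ]
            out.append(sum(vals) / len(vals))
    k = len(out) // 3
    return np.array(out[:k] + out[k : 2 * k] + out[2 * k :])
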