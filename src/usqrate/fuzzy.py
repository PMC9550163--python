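"""Fuzzy feature layer for pooled CNN feature maps.

The layer sits between a network's last max-pooling output and its dense
head. Each channel's spatial activation field (values in [0, r_max], the
ceiling of a capped ReLU) is fuzzified by three membership functions --
Gaussian G(x; q, sigma), triangular T(x; p, q, r) and the quadratic
S-shaped spline S(x; p, r) -- and each fuzzy map is collapsed back to one
crisp value by mean-of-maxima (MOM) defuzzification: the mean of the
*activation* values at the spatial positions where the membership degree is
maximal. Per channel this yields three crisp values, so a C-channel map
produces a 3C feature vector blocked as [G | T | S] (1536 for C=512).

Default parameters follow the capped-ReLU ceiling r_max = 6:
p = r_max/2 = 3, q = p + r_max/4 = 4.5, r = r_max = 6, sigma = r_max/4 = 1.5.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "R_MAX_DEFAULT",
    "MembershipParams",
    "membership_gaussian",
    "membership_triangular",
    "membership_s",
    "defuzzify_mom",
    "fuzzy_forward",
    "fuzzy_forward_with_masks",
]

R_MAX_DEFAULT = 6.0
#: relative tolerance for treating membership degrees as tied at the maximum
MOM_TIE_RTOL = 1e-6

MEMBERSHIP_ORDER = ("gaussian", "triangular", "s")


@dataclass(frozen=True)
class MembershipParams:
    """Shared parameters of the three membership functions.

    p < q < r are the triangular feet/peak; p and r bound the S-spline;
    q and sigma parameterise the Gaussian. The default rule ties them to
    the activation ceiling r_max: p = r_max/2, q = p + r_max/4, r = r_max.
    """

    p: float = R_MAX_DEFAULT / 2.0
    q: float = R_MAX_DEFAULT / 2.0 + R_MAX_DEFAULT / 4.0
    r: float = R_MAX_DEFAULT
    sigma: float = R_MAX_DEFAULT / 4.0
    r_max: float = R_MAX_DEFAULT

    def __post_init__(self) -> None:
        if not (self.p < self.q < self.r):
            raise ValueError(f"require p < q < r, got p={self.p}, q={self.q}, r={self.r}")
        if self.sigma <= 0:
            raise ValueError("sigma must be positive")
        if self.r_max <= 0:
            raise ValueError("r_max must be positive")

    @classmethod
    def from_r_max(cls, r_max: float, sigma: float | None = None) -> "MembershipParams":
        p = r_max / 2.0
        return cls(p=p, q=p + r_max / 4.0, r=r_max, sigma=sigma if sigma is not None else r_max / 4.0, r_max=r_max)


def membership_gaussian(x, params: MembershipParams):
    """G(x; q, sigma) = exp(-(x-q)^2 / (2 sigma^2))."""
    x = np.asarray(x, dtype=np.float64)
    out = np.exp(-((x - params.q) ** 2) / (2.0 * params.sigma**2))
    return out if out.ndim else float(out)


def membership_triangular(x, params: MembershipParams):
    """Triangle with feet p, r and peak 1 at q; 0 outside (p, r)."""
    p, q, r = params.p, params.q, params.r
    x = np.asarray(x, dtype=np.float64)
    rise = (x - p) / (q - p)
    fall = (r - x) / (r - q)
    out = np.where(x <= p, 0.0, np.where(x <= q, rise, np.where(x < r, fall, 0.0)))
    return out if out.ndim else float(out)


def membership_s(x, params: MembershipParams):
    """Quadratic S-spline: 0 below p, 1 above r, value 1/2 at (p+r)/2."""
    p, r = params.p, params.r
    x = np.asarray(x, dtype=np.float64)
    m = 0.5 * (p + r)
    lower = 2.0 * ((x - p) / (r - p)) ** 2
    upper = 1.0 - 2.0 * ((x - r) / (r - p)) ** 2
    out = np.where(x <= p, 0.0, np.where(x <= m, lower, np.where(x <= r, upper, 1.0)))
    return out if out.ndim else float(out)


_MEMBERSHIP_FN = {
    "gaussian": membership_gaussian,
    "triangular": membership_triangular,
    "s": membership_s,
}


def _max_mask(degrees: np.ndarray) -> np.ndarray:
    top = degrees.max()
    tol = MOM_TIE_RTOL * max(abs(top), 1e-300)
    return degrees >= top - tol


def defuzzify_mom(memberships: np.ndarray, crisp_domain: np.ndarray, collapse_to_degree: bool = False) -> float:
    """Mean-of-maxima defuzzification.

    Finds the maximum membership degree over the field (ties within
    relative tolerance 1e-6) and returns the mean of the crisp activation
    values at every position attaining it. With ``collapse_to_degree`` the
    mean of the maximal *degrees* is returned instead (a comparison variant
    that reduces to the max degree itself).
    """
    deg = np.asarray(memberships, dtype=np.float64)
    dom = np.asarray(crisp_domain, dtype=np.float64)
    if deg.size == 0:
        raise ValueError("empty membership field")
    if deg.shape != dom.shape:
        raise ValueError(f"shape mismatch: degrees {deg.shape} vs domain {dom.shape}")
    if deg.min() < -1e-12 or deg.max() > 1.0 + 1e-12:
        raise ValueError("membership degrees must lie in [0, 1]")
    mask = _max_mask(deg)
    src = deg if collapse_to_degree else dom
    return float(src[mask].mean())


def fuzzy_forward(
    feature_map: np.ndarray,
    params: MembershipParams | None = None,
    collapse_to_degree: bool = False,
) -> np.ndarray:
    """Fuzzify and defuzzify a pooled feature map into a 3C crisp vector.

    Parameters
    ----------
    feature_map
        H x W x C activations in [0, params.r_max].
    params
        Membership parameters; defaults to the r_max=6 rule.

    Returns
    -------
    numpy.ndarray
        Length 3C vector in block order [Gaussian | Triangular | S].
    """
    vec, _ = fuzzy_forward_with_masks(feature_map, params, collapse_to_degree)
    return vec


def fuzzy_forward_with_masks(
    feature_map: np.ndarray,
    params: MembershipParams | None = None,
    collapse_to_degree: bool = False,
) -> tuple[np.ndarray, np.ndarray]:
    """:func:`fuzzy_forward` returning also the maximal-position masks.

    The boolean mask array (3, H, W, C) records, per membership function
    and channel, which spatial positions attained the maximal degree; the
    training code uses it to route gradients (MOM acts as a selector, like
    max-pooling).
    """
    if params is None:
        params = MembershipParams()
    fmap = np.asarray(feature_map, dtype=np.float64)
    if fmap.ndim != 3:
        raise ValueError(f"expected an H x W x C map, got shape {fmap.shape}")
    if fmap.size == 0:
        raise ValueError("empty feature map")
    if fmap.min() < -1e-9 or fmap.max() > params.r_max + 1e-9:
        raise ValueError(f"activations must lie in [0, {params.r_max}]")

    h, w, c = fmap.shape
    flat = fmap.reshape(h * w, c)
    blocks = []
    masks = np.zeros((3, h * w, c), dtype=bool)
    for b, name in enumerate(MEMBERSHIP_ORDER):
        deg = _MEMBERSHIP_FN[name](flat, params)  # (HW, C)
        top = deg.max(axis=0)
        tol = MOM_TIE_RTOL * np.maximum(np.abs(top), 1e-300)
        mask = deg >= top - tol
        masks[b] = mask
        counts = mask.sum(axis=0)
        src = deg if collapse_to_degree else flat
        blocks.append((src * mask).sum(axis=0) / counts)
    return np.concatenate(blocks), masks.reshape(3, h, w, c)
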