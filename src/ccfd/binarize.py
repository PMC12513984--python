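"""Phansalkar local adaptive thresholding.

Phansalkar's method was designed for low-contrast images: the local
threshold over a circular window of radius ``radius_px`` is

    t = mu * (1 + p * exp(-q * mu) + k * (sigma / r - 1))

with local mean ``mu`` and local standard deviation ``sigma``.  The
exponential term boosts the threshold in dark regions, which is what makes
the method sensitive to the image's absolute intensity scale (and hence to
attenuation, slab choice and device).  Constants follow the original
method as implemented in the Fiji Auto Local Threshold plugin:
``(k, r, p, q) = (0.25, 0.5, 2.0, 10.0)``.

A pixel is classified as flow deficit when its intensity is less than or
equal to its local threshold (ties count as deficit; the all-zero image is
therefore 100% deficit).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import correlate
from skimage.morphology import disk

__all__ = ["PhansalkarParams", "FDMask", "phansalkar_threshold", "radius_um_to_px"]


@dataclass(frozen=True)
class PhansalkarParams:
    """Window radius and formula constants of the Phansalkar threshold."""

    radius_px: int = 4
    k: float = 0.25
    r: float = 0.5
    p: float = 2.0
    q: float = 10.0

    def __post_init__(self) -> None:
        if self.radius_px < 1:
            raise ValueError("radius_px must be >= 1")
        if self.r <= 0:
            raise ValueError("r must be positive")


@dataclass(frozen=True)
class FDMask:
    """Binary flow-deficit map (True = deficit) with physical pixel pitch."""

    mask: np.ndarray
    pixel_size_um: float
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.mask.ndim != 2:
            raise ValueError("mask must be 2-D")
        if self.mask.dtype != bool:
            raise ValueError("mask must be boolean")
        if self.pixel_size_um <= 0:
            raise ValueError("pixel_size_um must be positive")


def radius_um_to_px(radius_um: float, pixel_size_um: float) -> int:
    """Convert a physical window radius to pixels (rounded, at least 1)."""
    return max(1, int(round(radius_um / pixel_size_um)))


def phansalkar_threshold(
    img: np.ndarray,
    pixel_size_um: float,
    params: PhansalkarParams | None = None,
    provenance: dict | None = None,
) -> FDMask:
    """Binarize a [0, 1] image into flow vs flow-deficit pixels.

    Local statistics are computed over the circular (Euclidean) window of
    ``params.radius_px`` pixels with reflect padding at the borders; a
    pixel is a deficit iff ``img <= t`` with ``t`` the Phansalkar
    threshold.  Deterministic: identical input gives an identical mask.
    """
    if params is None:
        params = PhansalkarParams()
    if img.ndim != 2:
        raise ValueError("img must be 2-D")
    if not np.all(np.isfinite(img)):
        raise ValueError("img contains non-finite values")
    if img.min() < 0 or img.max() > 1:
        raise ValueError("img must be normalized to [0, 1]")
    if params.radius_px >= min(img.shape):
        raise ValueError(
            f"radius {params.radius_px} px must be smaller than the smallest "
            f"image dimension {min(img.shape)} px"
        )

    fp = disk(params.radius_px).astype(float)
    area = fp.sum()
    img = img.astype(float, copy=False)
    mu = correlate(img, fp, mode="reflect") / area
    m2 = correlate(img * img, fp, mode="reflect") / area
    sigma = np.sqrt(np.clip(m2 - mu * mu, 0.0, None))
    t = mu * (
        1.0
        + params.p * np.exp(-params.q * mu)
        + params.k * (sigma / params.r - 1.0)
    )
    mask = img <= t
    prov = dict(provenance or {})
    prov["phansalkar"] = {
        "radius_px": params.radius_px,
        "k": params.k,
        "r": params.r,
        "p": params.p,
        "q": params.q,
    }
    return FDMask(mask, pixel_size_um, prov)
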