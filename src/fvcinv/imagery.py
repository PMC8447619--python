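"""Fractional vegetation cover extraction from RGB aerial imagery.

Centimetre-scale aerial photographs of grassland are segmented into
vegetation and background pixels with the Excess Green Index,
``EGI = 2G - R - B``, which is strongly positive for green canopy and
near zero or negative for soil, litter and rock.  The image-level FVC is
the fraction of pixels classified as vegetation.

The segmentation threshold is traditionally picked by eye within an
empirical EGI range of 40-160.  For reproducibility this module instead
maximises the between-class variance of the EGI histogram over that same
range (a range-restricted Otsu criterion); a manual threshold can always
be supplied to override the automatic choice.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from PIL import Image

__all__ = [
    "SegmentationResult",
    "read_image",
    "compute_egi",
    "segment",
    "select_threshold",
    "image_fvc",
]

#: Empirical EGI threshold search range for grassland imagery.
DEFAULT_THRESHOLD_RANGE = (40, 160)


@dataclass(frozen=True)
class SegmentationResult:
    """Binary vegetation mask with the threshold that produced it.

    ``fvc`` is exactly ``mask.sum() / mask.size``.
    """

    mask: np.ndarray
    threshold: int
    fvc: float

    @property
    def n_vegetation(self) -> int:
        return int(self.mask.sum())


def read_image(path) -> np.ndarray:
    """Load a PNG or JPEG image as an (H, W, 3) uint8 RGB array."""
    with Image.open(path) as im:
        return np.asarray(im.convert("RGB"), dtype=np.uint8)


def compute_egi(img: np.ndarray) -> np.ndarray:
    """Excess Green Index, 2G - R - B, in signed integer arithmetic.

    Parameters
    ----------
    img : (H, W, 3) array of 8-bit RGB intensities, channel order R, G, B.

    Returns
    -------
    (H, W) int16 array with values in [-510, 510].
    """
    img = np.asarray(img)
    if img.ndim != 3 or img.shape[-1] != 3:
        raise ValueError(f"expected an (H, W, 3) RGB image, got shape {img.shape}")
    # promote before arithmetic: uint8 would wrap around for negative EGI
    r = img[..., 0].astype(np.int16)
    g = img[..., 1].astype(np.int16)
    b = img[..., 2].astype(np.int16)
    return 2 * g - r - b


def segment(egi: np.ndarray, threshold: float) -> SegmentationResult:
    """Classify pixels with EGI strictly greater than ``threshold`` as vegetation."""
    if not np.isfinite(threshold):
        raise ValueError("threshold must be finite")
    egi = np.asarray(egi)
    mask = egi > threshold
    fvc = float(mask.sum()) / mask.size
    return SegmentationResult(mask=mask, threshold=int(threshold), fvc=fvc)


def select_threshold(egi: np.ndarray, lo: int = 40, hi: int = 160) -> int:
    """Pick the integer threshold in [lo, hi] maximising between-class variance.

    Otsu's criterion restricted to the empirical EGI range: for each
    candidate t the pixels split into background (EGI <= t) and
    vegetation (EGI > t) and the between-class variance
    ``w0 * w1 * (mu0 - mu1)**2`` is evaluated; ties break toward the
    smaller threshold.

    Raises
    ------
    ValueError
        If ``lo > hi`` or the EGI grid is constant (unsegmentable).
    """
    if lo > hi:
        raise ValueError(f"invalid threshold range [{lo}, {hi}]")
    egi = np.asarray(egi, dtype=np.int64).ravel()
    if egi.min() == egi.max():
        raise ValueError("constant EGI grid: image cannot be segmented")

    # histogram over the full signed EGI support, then cumulative moments
    offset = -510
    counts = np.bincount(egi - offset, minlength=1021)
    values = np.arange(1021, dtype=np.float64) + offset
    cum_n = np.cumsum(counts)
    cum_s = np.cumsum(counts * values)
    n = cum_n[-1]
    s = cum_s[-1]

    candidates = np.arange(lo, hi + 1)
    idx = candidates - offset  # class 0 is EGI <= t, i.e. bins [0, idx]
    n0 = cum_n[idx].astype(np.float64)
    s0 = cum_s[idx]
    n1 = n - n0
    valid = (n0 > 0) & (n1 > 0)
    sigma_b = np.zeros(candidates.size)
    with np.errstate(invalid="ignore", divide="ignore"):
        mu0 = s0 / n0
        mu1 = (s - s0) / n1
        sb = (n0 / n) * (n1 / n) * (mu0 - mu1) ** 2
    sigma_b[valid] = sb[valid]
    # argmax returns the first maximum -> smaller-threshold tie-break
    return int(candidates[int(np.argmax(sigma_b))])


def image_fvc(
    img: np.ndarray,
    threshold: int | None = None,
    lo: int = 40,
    hi: int = 160,
) -> SegmentationResult:
    """End-to-end FVC extraction: EGI, threshold selection, segmentation.

    If ``threshold`` is None the range-restricted Otsu threshold over
    ``[lo, hi]`` is used; otherwise the supplied value is applied as-is.
    """
    egi = compute_egi(img)
    if threshold is None:
        threshold = select_threshold(egi, lo=lo, hi=hi)
    return segment(egi, threshold)


def overlay_mask(img: np.ndarray, mask: np.ndarray) -> np.ndarray:
    """Paint vegetation pixels green on a copy of the source image."""
    out = np.asarray(img).copy()
    out[np.asarray(mask, dtype=bool)] = (0, 200, 0)
    return out
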