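"""Contrast stretching and vegetation-index plant/soil segmentation.

The segmentation combines three vegetation indices computed from the
contrast-stretched image: excess green (ExG), modified excess green (MExG)
and the color index of vegetation extraction (CIVE).  The MExG − CIVE
difference image is thresholded with Otsu's method (plant = above threshold,
since vegetation is MExG-high and CIVE-low), a fixed 0.5 threshold is applied
to rescaled ExG, and a pixel is plant if either mask says so.  Small
connected components are then removed as noise.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from skimage.filters import threshold_otsu
from skimage.measure import label

from ._util import rescale01, round_half_away

__all__ = [
    "SegIndexImages",
    "stretch_limits",
    "stretch_contrast",
    "compute_seg_indices",
    "build_plant_mask",
    "remove_small_objects",
    "segment",
    "mask_iou",
]


def _check_rgb(image: np.ndarray) -> np.ndarray:
    image = np.asarray(image)
    if image.ndim != 3 or image.shape[2] != 3:
        raise ValueError(f"expected an H×W×3 RGB image, got shape {image.shape}")
    if image.shape[0] < 2 or image.shape[1] < 2:
        raise ValueError("image must be at least 2×2 (co-occurrence needs pixel pairs)")
    return image


def stretch_limits(channel: np.ndarray, lower_pct: float = 1.0, upper_pct: float = 99.0) -> tuple[float, float]:
    """Original lower/upper limits for contrast stretching.

    The limits are the 1st and 99th percentiles of the channel's pixel
    values (linear interpolation between order statistics), so that the
    bottom and top 1% of values saturate.
    """
    channel = np.asarray(channel, dtype=np.float64)
    lo, hi = np.percentile(channel, [lower_pct, upper_pct])
    return float(lo), float(hi)


def _stretch_channel(channel: np.ndarray, lo: float, hi: float) -> np.ndarray:
    """Linearly map [lo, hi] to [0, 255], saturating outside; half-away rounding."""
    channel = np.asarray(channel, dtype=np.float64)
    if hi == lo:
        # No contrast to stretch; the linear map is undefined.
        return channel.astype(np.uint8)
    out = (channel - lo) * 255.0 / (hi - lo)
    out = np.clip(out, 0.0, 255.0)
    return round_half_away(out).astype(np.uint8)


def stretch_contrast(image: np.ndarray) -> np.ndarray:
    """Stretch each channel independently, saturating the bottom/top 1%.

    Parameters
    ----------
    image:
        8-bit H×W×3 RGB raster.

    Returns
    -------
    uint8 H×W×3 raster with each channel linearly remapped so its 1st
    percentile lands at 0 and its 99th at 255.  A flat channel is returned
    unchanged.
    """
    image = _check_rgb(image)
    out = np.empty(image.shape, dtype=np.uint8)
    for c in range(3):
        lo, hi = stretch_limits(image[..., c])
        out[..., c] = _stretch_channel(image[..., c], lo, hi)
    return out


@dataclass
class SegIndexImages:
    """The three vegetation-index rasters used for segmentation.

    ``exg``/``mexg``/``cive`` are the raw index values; the ``*_01``
    attributes are min-max rescaled copies in [0, 1].
    """

    exg: np.ndarray
    mexg: np.ndarray
    cive: np.ndarray
    exg_01: np.ndarray
    mexg_01: np.ndarray
    cive_01: np.ndarray


def compute_seg_indices(image: np.ndarray) -> SegIndexImages:
    """ExG, MExG and CIVE index images from a (stretched) RGB image.

    ExG is (2G−R−B)/(R+G+B) with the value −1 assigned where R=G=B=0;
    MExG = 1.262G − 0.884R − 0.311B; CIVE = 0.441R − 0.811G + 0.385B
    + 18.78745.  Each raster is also min-max rescaled to [0, 1].
    """
    image = _check_rgb(image)
    r = image[..., 0].astype(np.float64)
    g = image[..., 1].astype(np.float64)
    b = image[..., 2].astype(np.float64)
    total = r + g + b
    exg = np.full_like(total, -1.0)
    nz = total > 0
    exg[nz] = (2.0 * g[nz] - r[nz] - b[nz]) / total[nz]
    mexg = 1.262 * g - 0.884 * r - 0.311 * b
    cive = 0.441 * r - 0.811 * g + 0.385 * b + 18.78745
    return SegIndexImages(
        exg=exg,
        mexg=mexg,
        cive=cive,
        exg_01=rescale01(exg),
        mexg_01=rescale01(mexg),
        cive_01=rescale01(cive),
    )


def build_plant_mask(
    indices: SegIndexImages,
    exg_threshold: float = 0.5,
    min_object_pixels: int = 300,
    connectivity: int = 8,
) -> np.ndarray:
    """Combine the index images into the final boolean plant mask.

    M1 thresholds the MExG−CIVE difference image with Otsu's method (256
    histogram bins; plant = strictly above threshold), M2 thresholds rescaled
    ExG at ``exg_threshold`` (strictly above).  A pixel is plant if either
    mask is set; connected plant components of ``min_object_pixels`` or fewer
    pixels are then removed as noise.

    Returns a boolean H×W array, True = plant.  Raises ``ValueError`` if the
    difference image is constant (Otsu has no threshold to find).
    """
    diff = indices.mexg_01 - indices.cive_01
    if np.min(diff) == np.max(diff):
        raise ValueError("cannot threshold a constant MExG−CIVE difference image")
    thresh = threshold_otsu(diff, nbins=256)
    m1 = diff > thresh
    m2 = indices.exg_01 > exg_threshold
    mask = m1 | m2
    return remove_small_objects(mask, min_pixels=min_object_pixels, connectivity=connectivity)


def remove_small_objects(mask: np.ndarray, min_pixels: int = 300, connectivity: int = 8) -> np.ndarray:
    """Drop connected plant components with ``min_pixels`` or fewer pixels.

    The bound is inclusive: a component of exactly ``min_pixels`` pixels is
    removed, one of ``min_pixels + 1`` survives.
    """
    mask = np.asarray(mask, dtype=bool)
    if min_pixels <= 0 or not mask.any():
        return mask.copy()
    lab = label(mask, connectivity=2 if connectivity == 8 else 1)
    sizes = np.bincount(lab.ravel())
    keep = sizes > min_pixels
    keep[0] = False
    return keep[lab]


def segment(
    image: np.ndarray,
    exg_threshold: float = 0.5,
    min_object_pixels: int = 300,
    connectivity: int = 8,
) -> np.ndarray:
    """Plant mask straight from a contrast-stretched RGB image (convenience)."""
    return build_plant_mask(
        compute_seg_indices(image),
        exg_threshold=exg_threshold,
        min_object_pixels=min_object_pixels,
        connectivity=connectivity,
    )


def mask_iou(a: np.ndarray, b: np.ndarray) -> float:
    """Intersection-over-union of two boolean masks (1.0 if both empty)."""
    a = np.asarray(a, dtype=bool)
    b = np.asarray(b, dtype=bool)
    union = np.logical_or(a, b).sum()
    if union == 0:
        return 1.0
    return float(np.logical_and(a, b).sum() / union)
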