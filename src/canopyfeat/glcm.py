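"""NA-aware symmetric gray-level co-occurrence matrices and texture statistics.

Each transform raster is quantized (without the mask) to 256 gray levels,
the mask is applied, and symmetric co-occurrence matrices are accumulated at
displacement d = 1 along the 0° (same row) and 90° (same column) scanning
directions.  A pixel pair contributes only if both members are plant pixels;
each valid pair is counted in both orders, making the matrix symmetric.
Nine Haralick-style statistics are computed per direction and averaged:
maximum probability (MP), mean (MEA), variance (VAR), correlation (COR),
angular second moment (ASM), entropy (ENT, log base 2 with 0·log 0 = 0),
dissimilarity (DIS), contrast (CON) and inverse difference moment (IDM).
MEA and VAR use the single-margin forms valid for a symmetric matrix.

35 transforms × 9 statistics = 315 texture features per image.
"""

from __future__ import annotations

import math

import numpy as np

from ._util import round_half_away
from .transforms import TRANSFORM_NAMES, TransformedImage

__all__ = [
    "TEXTURE_STAT_NAMES",
    "EmptyGlcmError",
    "quantize",
    "compute_glcm",
    "normalize_glcm",
    "texture_stats",
    "texture_features_for_transform",
    "all_texture_features",
    "texture_feature_names",
]

TEXTURE_STAT_NAMES: tuple[str, ...] = (
    "MP", "MEA", "VAR", "COR", "ASM", "ENT", "DIS", "CON", "IDM",
)

#: NA marker in quantized rasters.
NA = -1


class EmptyGlcmError(ValueError):
    """No valid pixel pair exists for a transform/direction."""

    def __init__(self, transform: str = "", direction: int | None = None):
        self.transform = transform
        self.direction = direction
        where = f" for transform {transform!r}" if transform else ""
        if direction is not None:
            where += f" at {direction}°"
        super().__init__(f"empty GLCM{where}: no valid pixel pair")


def quantize(t: TransformedImage | np.ndarray, mask: np.ndarray | None = None, levels: int = 256) -> np.ndarray:
    """Quantize a transform to integer gray levels, then apply the mask.

    The *unmasked* raster is linearly min-max mapped to [0, levels−1] and
    rounded (half away from zero); masked pixels are then set to the NA
    marker (−1).  A constant raster maps to all zeros.
    """
    if isinstance(t, TransformedImage):
        raster = t.unmasked
        if mask is None:
            mask = ~np.isnan(t.values)
    else:
        raster = np.asarray(t, dtype=np.float64)
        if mask is None:
            mask = np.ones(raster.shape, dtype=bool)
    lo = raster.min()
    hi = raster.max()
    if hi == lo:
        q = np.zeros(raster.shape, dtype=np.int16)
    else:
        scaled = (raster - lo) * (levels - 1) / (hi - lo)
        q = round_half_away(scaled).astype(np.int16)
    q[~np.asarray(mask, dtype=bool)] = NA
    return q


_OFFSETS = {
    # direction -> (row offset, column offset) of the second pair member
    0: (0, 1),
    45: (1, 1),
    90: (1, 0),
    135: (1, -1),
}


def _pair_views(q: np.ndarray, d: int, direction: int) -> tuple[np.ndarray, np.ndarray]:
    dr, dc = _OFFSETS[direction]
    dr, dc = dr * d, dc * d
    h, w = q.shape
    if dr >= h or abs(dc) >= w:
        return q[:0, :0], q[:0, :0]
    a = q[: h - dr, :]
    b = q[dr:, :]
    if dc > 0:
        a, b = a[:, : w - dc], b[:, dc:]
    elif dc < 0:
        a, b = a[:, -dc:], b[:, : w + dc]
    return a, b


def compute_glcm(q: np.ndarray, d: int = 1, direction: int = 0, levels: int = 256,
                 transform: str = "") -> np.ndarray:
    """Symmetric co-occurrence count matrix P(i, j, d, θ).

    Pairs lie along ``direction`` degrees at displacement ``d``; pairs with
    an NA member are skipped; every valid pair increments both (i, j) and
    (j, i), so the total count is twice the number of valid pairs.

    Raises :class:`EmptyGlcmError` if no valid pair exists.
    """
    if direction not in _OFFSETS:
        raise ValueError(f"direction must be one of {sorted(_OFFSETS)}, got {direction}")
    q = np.asarray(q)
    a, b = _pair_views(q, d, direction)
    valid = (a != NA) & (b != NA)
    ai = a[valid].astype(np.int64)
    bi = b[valid].astype(np.int64)
    if ai.size == 0:
        raise EmptyGlcmError(transform, direction)
    flat = np.bincount(ai * levels + bi, minlength=levels * levels)
    counts = flat.reshape(levels, levels)
    return counts + counts.T


def normalize_glcm(counts: np.ndarray) -> np.ndarray:
    """Normalize a count matrix to a joint probability matrix (sums to 1)."""
    counts = np.asarray(counts, dtype=np.float64)
    total = counts.sum()
    if total <= 0:
        raise EmptyGlcmError()
    return counts / total


def texture_stats(p: np.ndarray) -> dict[str, float]:
    """The nine texture statistics of one normalized symmetric GLCM.

    COR is NaN when VAR = 0 (a single-gray-level region has no correlation
    to speak of).
    """
    p = np.asarray(p, dtype=np.float64)
    levels = p.shape[0]
    i = np.arange(levels, dtype=np.float64)
    margin = p.sum(axis=1)  # equals the other margin for a symmetric matrix
    mea = float(np.dot(i, margin))
    var = float(np.dot((i - mea) ** 2, margin))
    diff = i[:, None] - i[None, :]
    if var > 0.0:
        cor = float(np.sum((i[:, None] - mea) * (i[None, :] - mea) * p) / var)
    else:
        cor = math.nan
    nz = p > 0
    ent = float(-np.sum(p[nz] * np.log2(p[nz])))
    return {
        "MP": float(p.max()),
        "MEA": mea,
        "VAR": var,
        "COR": cor,
        "ASM": float(np.sum(p * p)),
        "ENT": ent,
        "DIS": float(np.sum(np.abs(diff) * p)),
        "CON": float(np.sum(diff**2 * p)),
        "IDM": float(np.sum(p / (1.0 + diff**2))),
    }


def texture_features_for_transform(
    q: np.ndarray,
    d: int = 1,
    directions: tuple[int, ...] = (0, 90),
    levels: int = 256,
    transform: str = "",
) -> dict[str, float]:
    """Direction-averaged texture statistics for one quantized transform.

    Statistics are computed per scanning direction and averaged element-wise;
    a NaN in any direction (e.g. undefined COR) makes the average NaN.
    Propagates :class:`EmptyGlcmError` if any direction has no valid pair.
    """
    per_dir = [
        texture_stats(normalize_glcm(compute_glcm(q, d=d, direction=th, levels=levels,
                                                  transform=transform)))
        for th in directions
    ]
    return {
        stat: float(np.mean([s[stat] for s in per_dir]))
        for stat in TEXTURE_STAT_NAMES
    }


def texture_feature_names(transforms: tuple[str, ...] = TRANSFORM_NAMES) -> list[str]:
    """The 315 texture feature column names, transform-major order."""
    return [f"{t}_{s}" for t in transforms for s in TEXTURE_STAT_NAMES]


def all_texture_features(
    bank: dict[str, TransformedImage],
    mask: np.ndarray,
    d: int = 1,
    directions: tuple[int, ...] = (0, 90),
    levels: int = 256,
) -> dict[str, float]:
    """All 315 named texture features for one image's transform bank."""
    out: dict[str, float] = {}
    for name in TRANSFORM_NAMES:
        q = quantize(bank[name], mask=mask, levels=levels)
        stats = texture_features_for_transform(q, d=d, directions=directions,
                                               levels=levels, transform=name)
        for stat, value in stats.items():
            out[f"{name}_{stat}"] = value
    return out
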