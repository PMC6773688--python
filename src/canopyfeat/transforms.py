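"""The 35-image transform bank.

Each contrast-stretched RGB image is expanded into 35 real-valued rasters:
the three raw channels, the channels of four theoretical color spaces
(CIE 1931 XYZ, CIE 1976 L*a*b*, HSI, Y'CbCr) and twenty empirical
vegetation indices.  Index formulas operate on the stretched 8-bit R, G, B
values; division by zero is allowed to produce NaN/±inf, which the
sanitization step replaces by the raster's minimum (NaN, −inf) or maximum
(+inf) finite value before the plant mask is applied.

Values are kept at full double precision throughout; only the raw channels
are integer-valued.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from skimage.color import rgb2xyz, xyz2lab
from skimage.color.colorconv import xyz_from_rgb

from ._util import rescale01

__all__ = [
    "TRANSFORM_NAMES",
    "VEGETATION_INDEX_NAMES",
    "TransformedImage",
    "color_space_channels",
    "vegetation_index",
    "sanitize",
    "sanitize_and_mask",
    "transform_bank",
]

#: The 35 transform names, in canonical (table) order: original channels,
#: theoretical color-space channels, then empirical vegetation indices.
TRANSFORM_NAMES: tuple[str, ...] = (
    "R", "G", "B",
    "X", "Y", "Z",
    "Lstar", "astar", "bstar",
    "H", "S", "I",
    "Yprime", "Cb", "Cr",
    "NR", "NG", "NB",
    "ExR", "ExB", "ExGR",
    "GBD", "RBD", "RGD",
    "GRR", "GBR",
    "NGRD", "NGBD", "MNGRD",
    "VD", "RGBVI", "CI",
    "CIVE", "TGI", "MExG",
)

VEGETATION_INDEX_NAMES: tuple[str, ...] = TRANSFORM_NAMES[15:]


@dataclass
class TransformedImage:
    """A named, sanitized transform raster.

    ``values`` carries NaN at masked (non-plant) pixels; ``unmasked`` is the
    same raster before mask application (used for gray-level quantization,
    which rescales over the full image).
    """

    name: str
    values: np.ndarray
    unmasked: np.ndarray

    @property
    def plant_pixel_count(self) -> int:
        """Number of non-NA (plant) pixels, N."""
        return int(np.count_nonzero(~np.isnan(self.values)))


def _rgb01(image: np.ndarray) -> np.ndarray:
    return np.asarray(image, dtype=np.float64) / 255.0


def _hsi(rgb01: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    # Gonzalez & Woods arccos formulation; H in degrees [0, 360), 0 where
    # undefined (achromatic pixels); S in [0, 1]; I = (R+G+B)/3 in [0, 1].
    r, g, b = rgb01[..., 0], rgb01[..., 1], rgb01[..., 2]
    intensity = (r + g + b) / 3.0
    total = r + g + b
    s = np.zeros_like(total)
    nz = total > 0
    s[nz] = 1.0 - 3.0 * np.minimum(np.minimum(r, g), b)[nz] / total[nz]
    num = 0.5 * ((r - g) + (r - b))
    den = np.sqrt((r - g) ** 2 + (r - b) * (g - b))
    h = np.zeros_like(total)
    ok = den > 0
    theta = np.degrees(np.arccos(np.clip(num[ok] / den[ok], -1.0, 1.0)))
    h[ok] = np.where(b[ok] > g[ok], 360.0 - theta, theta)
    return h, s, intensity


def _ycbcr(image: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    # ITU-R BT.601 full-range on 8-bit values.
    r = image[..., 0].astype(np.float64)
    g = image[..., 1].astype(np.float64)
    b = image[..., 2].astype(np.float64)
    yp = 0.299 * r + 0.587 * g + 0.114 * b
    cb = 128.0 - 0.168736 * r - 0.331264 * g + 0.5 * b
    cr = 128.0 + 0.5 * r - 0.418688 * g - 0.081312 * b
    return yp, cb, cr


def color_space_channels(image: np.ndarray, assume_linear_rgb: bool = False) -> dict[str, np.ndarray]:
    """The 12 theoretical color-space channel rasters.

    XYZ (CIE 1931, D65 illuminant, 2° standard observer) and L*a*b*
    (CIE 1976, D65) treat the 8-bit values as nonlinear sRGB by default and
    inverse-compand them first; set ``assume_linear_rgb`` to apply the
    conversion matrix to the raw values directly.  HSI uses the arccos hue
    formulation with I scaled to [0, 1]; Y'CbCr uses BT.601 full-range
    coefficients on the 8-bit values.
    """
    rgb01 = _rgb01(image)
    if assume_linear_rgb:
        xyz = rgb01 @ xyz_from_rgb.T.astype(np.float64)
    else:
        xyz = rgb2xyz(rgb01)
    lab = xyz2lab(xyz)
    h, s, i = _hsi(rgb01)
    yp, cb, cr = _ycbcr(np.asarray(image))
    return {
        "X": xyz[..., 0], "Y": xyz[..., 1], "Z": xyz[..., 2],
        "Lstar": lab[..., 0], "astar": lab[..., 1], "bstar": lab[..., 2],
        "H": h, "S": s, "I": i,
        "Yprime": yp, "Cb": cb, "Cr": cr,
    }


def _index_formulas() -> dict[str, callable]:
    return {
        "NR": lambda r, g, b: r / (r + g + b),
        "NG": lambda r, g, b: g / (r + g + b),
        "NB": lambda r, g, b: b / (r + g + b),
        "ExR": lambda r, g, b: (1.4 * r - g) / (r + g + b),
        "ExB": lambda r, g, b: (1.4 * b - g) / (r + g + b),
        "ExGR": lambda r, g, b: (3.0 * g - 2.4 * r - b) / (r + g + b),
        "GBD": lambda r, g, b: g - b,
        "RBD": lambda r, g, b: r - b,
        "RGD": lambda r, g, b: r - g,
        "GRR": lambda r, g, b: g / r,
        "GBR": lambda r, g, b: g / b,
        "NGRD": lambda r, g, b: (g - r) / (g + r),
        "NGBD": lambda r, g, b: (g - b) / (g + b),
        "MNGRD": lambda r, g, b: (g**2 - r**2) / (g**2 + r**2),
        "VD": lambda r, g, b: (2.0 * g - b - r) / (2.0 * g + b + r),
        "RGBVI": lambda r, g, b: (g**2 - b * r) / (g**2 + b * r),
        "CI": lambda r, g, b: 2.0 * b / (r + b),
        "CIVE": lambda r, g, b: 0.441 * r - 0.811 * g + 0.385 * b + 18.78745,
        "TGI": lambda r, g, b: 95.0 * g - 35.0 * r - 60.0 * b,
        "MExG": lambda r, g, b: 1.262 * g - 0.884 * r - 0.311 * b,
    }


def vegetation_index(image: np.ndarray, name: str) -> np.ndarray:
    """Evaluate one empirical vegetation index on the 8-bit R, G, B values.

    Zero denominators yield NaN/±inf, to be handled by :func:`sanitize`.
    """
    formulas = _index_formulas()
    if name not in formulas:
        raise KeyError(f"unknown vegetation index {name!r}; known: {sorted(formulas)}")
    r = np.asarray(image[..., 0], dtype=np.float64)
    g = np.asarray(image[..., 1], dtype=np.float64)
    b = np.asarray(image[..., 2], dtype=np.float64)
    with np.errstate(divide="ignore", invalid="ignore"):
        return formulas[name](r, g, b)


def sanitize(raster: np.ndarray) -> np.ndarray:
    """Replace NaN and −inf by the raster's minimum finite value, +inf by its maximum.

    Raises ``ValueError`` if no finite value exists.
    """
    raster = np.asarray(raster, dtype=np.float64)
    finite = np.isfinite(raster)
    if not finite.any():
        raise ValueError("raster has no finite values to sanitize against")
    if finite.all():
        return raster.copy()
    lo = raster[finite].min()
    hi = raster[finite].max()
    out = raster.copy()
    out[np.isnan(raster) | np.isneginf(raster)] = lo
    out[np.isposinf(raster)] = hi
    return out


def sanitize_and_mask(raster: np.ndarray, mask: np.ndarray, name: str = "") -> TransformedImage:
    """Sanitize a raw transform raster and apply the plant mask on top."""
    unmasked = sanitize(raster)
    values = unmasked.copy()
    values[~np.asarray(mask, dtype=bool)] = np.nan
    return TransformedImage(name=name, values=values, unmasked=unmasked)


def transform_bank(
    image: np.ndarray,
    mask: np.ndarray,
    assume_linear_rgb: bool = False,
) -> dict[str, TransformedImage]:
    """All 35 sanitized, masked transforms of a contrast-stretched image.

    Returns an ordered mapping keyed by :data:`TRANSFORM_NAMES`; the R, G, B
    entries are the stretched channels themselves.
    """
    image = np.asarray(image)
    mask = np.asarray(mask, dtype=bool)
    if image.shape[:2] != mask.shape:
        raise ValueError("image and mask shapes disagree")
    raw: dict[str, np.ndarray] = {
        "R": image[..., 0].astype(np.float64),
        "G": image[..., 1].astype(np.float64),
        "B": image[..., 2].astype(np.float64),
    }
    raw.update(color_space_channels(image, assume_linear_rgb=assume_linear_rgb))
    for name in VEGETATION_INDEX_NAMES:
        raw[name] = vegetation_index(image, name)
    return {name: sanitize_and_mask(raw[name], mask, name=name) for name in TRANSFORM_NAMES}
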