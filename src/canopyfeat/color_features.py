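"""Per-transform color moment statistics.

Four statistics are computed over the plant (non-NA) pixels of each
transform: mean μ, standard deviation σ, skewness θ and kurtosis δ, all in
their *population* form (denominator N, not N−1) — the canopy image is
treated as the whole pixel population rather than a sample.  With 35
transforms this yields 35 × 4 = 140 color features per image.

When σ = 0 (a flat transform over the plant region) skewness and kurtosis
are 0/0; they are reported as NaN rather than a fabricated number.
"""

from __future__ import annotations

import math

import numpy as np

from .transforms import TRANSFORM_NAMES, TransformedImage

__all__ = ["COLOR_STAT_NAMES", "color_stats", "all_color_features", "color_feature_names"]

COLOR_STAT_NAMES: tuple[str, ...] = ("mu", "sigma", "skew", "kurt")


def color_stats(t: TransformedImage | np.ndarray) -> dict[str, float]:
    """Population mean, sd, skewness and kurtosis of a transform's plant pixels.

    NA (NaN) pixels are excluded.  Raises ``ValueError`` if no plant pixel
    remains.
    """
    values = t.values if isinstance(t, TransformedImage) else np.asarray(t, dtype=np.float64)
    x = values[~np.isnan(values)]
    n = x.size
    if n == 0:
        raise ValueError("no plant pixels: cannot compute color statistics")
    mu = float(x.mean())
    dev = x - mu
    var = float(np.mean(dev**2))
    sigma = math.sqrt(var)
    if sigma == 0.0:
        skew = math.nan
        kurt = math.nan
    else:
        skew = float(np.mean(dev**3)) / sigma**3
        kurt = float(np.mean(dev**4)) / sigma**4
    return {"mu": mu, "sigma": sigma, "skew": skew, "kurt": kurt}


def color_feature_names(transforms: tuple[str, ...] = TRANSFORM_NAMES) -> list[str]:
    """The 140 color feature column names, transform-major order."""
    return [f"{t}_{s}" for t in transforms for s in COLOR_STAT_NAMES]


def all_color_features(bank: dict[str, TransformedImage]) -> dict[str, float]:
    """All 140 named color features for one image's transform bank."""
    out: dict[str, float] = {}
    for name in TRANSFORM_NAMES:
        stats = color_stats(bank[name])
        for stat, value in stats.items():
            out[f"{name}_{stat}"] = value
    return out
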