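"""Small numeric helpers shared across the pipeline."""

from __future__ import annotations

import numpy as np


def round_half_away(x: np.ndarray | float) -> np.ndarray:
    """Round half away from zero (for non-negative data: round half up).

    numpy's ``round`` rounds half to even; the pipeline pins half-away
    rounding so that contrast stretching and gray-level quantization are
    bit-exact and reproducible across platforms.
    """
    x = np.asarray(x, dtype=np.float64)
    return np.sign(x) * np.floor(np.abs(x) + 0.5)


def rescale01(values: np.ndarray) -> np.ndarray:
    """Min-max rescale a raster to [0, 1]; a constant raster maps to all zeros."""
    values = np.asarray(values, dtype=np.float64)
    lo = np.nanmin(values)
    hi = np.nanmax(values)
    if hi == lo:
        return np.zeros_like(values)
    return (values - lo) / (hi - lo)
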