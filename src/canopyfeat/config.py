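"""Pipeline configuration.

Every convention the underlying method leaves open is pinned here with an
explicit default, so a feature table can be reproduced bit-for-bit from the
sidecar that records the configuration it was built with.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field


@dataclass(frozen=True)
class PipelineConfig:
    """Knobs of the feature-extraction pipeline.

    Parameters
    ----------
    min_object_pixels:
        Connected plant components with this many pixels or fewer are removed
        from the mask (inclusive bound).
    exg_threshold:
        Threshold on the rescaled excess-green image for the second
        segmentation mask; pixels strictly above count as plant.
    connectivity:
        Pixel connectivity (4 or 8) used when labelling plant components for
        small-object removal.
    assume_linear_rgb:
        If False (default) 8-bit values are treated as nonlinear sRGB and
        inverse-companded before the XYZ / L*a*b* conversion; if True the
        matrix is applied to the raw values directly.
    gray_levels:
        Number of gray levels transforms are quantized to before building
        co-occurrence matrices.
    displacement:
        Pixel displacement ``d`` between the two members of a co-occurrence
        pair.
    directions:
        Scanning directions in degrees; texture statistics are averaged over
        them. 0 and 90 are the defaults; 45 and 135 are also supported.
    """

    min_object_pixels: int = 300
    exg_threshold: float = 0.5
    connectivity: int = 8
    assume_linear_rgb: bool = False
    gray_levels: int = 256
    displacement: int = 1
    directions: tuple[int, ...] = (0, 90)

    def __post_init__(self) -> None:
        if self.connectivity not in (4, 8):
            raise ValueError(f"connectivity must be 4 or 8, got {self.connectivity}")
        if self.gray_levels < 2 or self.gray_levels > 256:
            raise ValueError("gray_levels must be in [2, 256]")
        if self.displacement < 1:
            raise ValueError("displacement must be >= 1")
        bad = set(self.directions) - {0, 45, 90, 135}
        if bad:
            raise ValueError(f"unsupported directions: {sorted(bad)}")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["directions"] = list(self.directions)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        if "directions" in d:
            d["directions"] = tuple(d["directions"])
        return cls(**d)
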