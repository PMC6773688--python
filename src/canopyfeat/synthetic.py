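"""Synthetic canopy scene generator with ground-truth masks.

Renders soil-textured backgrounds overlaid with clusters of elliptical
"leaflets" (three per cluster, mimicking trifoliolate soybean leaves) in
jittered greens, with optional shadow regions.  The union of rendered
leaflet ellipses is the ground-truth plant mask, which makes every stage of
the extraction pipeline testable without any field imagery.

Scenes are fully reproducible from (params, seed).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd
from skimage.draw import ellipse

__all__ = ["CanopyParams", "CanopyScene", "DIFFICULTIES", "generate_scene", "generate_suite"]


@dataclass(frozen=True)
class CanopyParams:
    """Generator parameters for one canopy scene.

    Colors are 8-bit RGB means; ``soil_noise`` is the relative sd of the
    per-pixel multiplicative soil texture; ``leaf_jitter`` is the sd of the
    per-leaflet color offset and ``pixel_noise`` the sd of per-pixel
    additive noise on foliage.  ``shadow_fraction`` is the approximate
    fraction of the frame darkened by shadow ellipses.
    """

    height: int = 192
    width: int = 256
    n_clusters: int = 14
    leaflets_per_cluster: int = 3
    leaflet_axes: tuple[float, float] = (16.0, 7.5)
    leaflet_axes_jitter: float = 0.15
    leaf_rgb: tuple[int, int, int] = (60, 150, 55)
    leaf_jitter: float = 10.0
    pixel_noise: float = 5.0
    soil_rgb: tuple[int, int, int] = (120, 95, 70)
    soil_noise: float = 0.08
    shadow_fraction: float = 0.0
    shadow_strength: float = 0.55

    def __post_init__(self) -> None:
        if self.height < 2 or self.width < 2:
            raise ValueError("scene must be at least 2×2")
        for c in (*self.leaf_rgb, *self.soil_rgb):
            if not 0 <= c <= 255:
                raise ValueError("colors must be 8-bit")
        if self.n_clusters < 0:
            raise ValueError("n_clusters must be >= 0")


#: Difficulty presets: "easy" has saturated foliage and no shadows; "hard"
#: adds shadows and desaturates the leaves toward the soil hue.
DIFFICULTIES: dict[str, CanopyParams] = {
    "easy": CanopyParams(),
    "hard": CanopyParams(
        leaf_rgb=(85, 125, 70),
        leaf_jitter=24.0,
        leaflet_axes_jitter=0.25,
        soil_noise=0.13,
        shadow_fraction=0.25,
    ),
}


@dataclass
class CanopyScene:
    """A rendered scene: 8-bit RGB image, boolean truth mask, and provenance."""

    image: np.ndarray
    truth_mask: np.ndarray
    params: CanopyParams
    seed: int


def generate_scene(params: CanopyParams = CanopyParams(), seed: int = 0) -> CanopyScene:
    """Render one canopy scene deterministically from (params, seed)."""
    rng = np.random.default_rng(np.random.SeedSequence([seed]))
    h, w = params.height, params.width
    soil = np.asarray(params.soil_rgb, dtype=np.float64)
    img = soil[None, None, :] * (1.0 + params.soil_noise * rng.standard_normal((h, w, 1)))
    truth = np.zeros((h, w), dtype=bool)

    ax_r, ax_c = params.leaflet_axes
    # Keep cluster centers inset from the frame border so no plant is clipped
    # into a fragment smaller than any real early-vegetative plant; the frame
    # is centered on the plot, as in canopy scouting imagery.
    margin = 0.8 * ax_r * 1.2 + ax_r * (1.0 + 2.0 * params.leaflet_axes_jitter)
    for _ in range(params.n_clusters):
        cr = rng.uniform(margin, h - margin) if h > 2 * margin else rng.uniform(0, h)
        cc = rng.uniform(margin, w - margin) if w > 2 * margin else rng.uniform(0, w)
        base_angle = rng.uniform(0, 2 * np.pi)
        for k in range(params.leaflets_per_cluster):
            angle = base_angle + k * 2 * np.pi / max(params.leaflets_per_cluster, 1)
            angle += rng.normal(0, 0.25)
            # leaflet center offset outward so the cluster forms a rosette
            dist = ax_r * 0.8 * rng.uniform(0.7, 1.2)
            lr = cr + dist * np.sin(angle)
            lc = cc + dist * np.cos(angle)
            a = max(2.0, ax_r * (1 + params.leaflet_axes_jitter * rng.standard_normal()))
            b = max(1.5, ax_c * (1 + params.leaflet_axes_jitter * rng.standard_normal()))
            rr, cc_ = ellipse(lr, lc, a, b, shape=(h, w), rotation=angle)
            if rr.size == 0:
                continue
            color = np.asarray(params.leaf_rgb, dtype=np.float64) + params.leaf_jitter * rng.standard_normal(3)
            img[rr, cc_, :] = color[None, :] + params.pixel_noise * rng.standard_normal((rr.size, 3))
            truth[rr, cc_] = True

    if params.shadow_fraction > 0:
        mean_area = np.pi * (0.18 * h) * (0.18 * w)
        n_shadows = max(1, int(round(params.shadow_fraction * h * w / mean_area)))
        for _ in range(n_shadows):
            rr, cc_ = ellipse(
                rng.uniform(0, h), rng.uniform(0, w),
                0.18 * h * rng.uniform(0.6, 1.4), 0.18 * w * rng.uniform(0.6, 1.4),
                shape=(h, w), rotation=rng.uniform(0, np.pi),
            )
            img[rr, cc_, :] *= params.shadow_strength

    image = np.clip(np.rint(img), 0, 255).astype(np.uint8)
    return CanopyScene(image=image, truth_mask=truth, params=params, seed=seed)


# planting/measuring windows typical of early-vegetative scouting at the
# four synthetic locations
_LOCATION_DATES = {
    1: ("2016-05-20", "2016-06-21"),
    2: ("2016-05-21", "2016-06-23"),
    3: ("2016-06-03", "2016-07-06"),
    4: ("2016-06-04", "2016-07-10"),
}


def generate_suite(
    n_scenes: int,
    out_dir: str | Path,
    difficulties: tuple[str, ...] = ("easy",),
    seed: int = 0,
) -> pd.DataFrame:
    """Write ``n_scenes`` scenes + truth masks + a pipeline-ready manifest.

    Scenes cycle through the difficulty presets and through synthetic
    locations 1–4 (each with its own planting/measuring dates).  Returns the
    manifest as a DataFrame; it is also written to ``manifest.csv``.
    """
    if n_scenes < 1:
        raise ValueError("n_scenes must be >= 1")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rows = []
    for i in range(n_scenes):
        difficulty = difficulties[i % len(difficulties)]
        params = DIFFICULTIES[difficulty]
        scene = generate_scene(params, seed=int(np.random.SeedSequence([seed, i]).generate_state(1)[0] % 2**31))
        image_id = f"scene_{i:03d}_{difficulty}"
        img_path = out_dir / f"{image_id}.png"
        mask_path = out_dir / f"{image_id}_mask.png"
        iio.imwrite(img_path, scene.image)
        iio.imwrite(mask_path, (scene.truth_mask * 255).astype(np.uint8))
        location = i % 4 + 1
        planting, measuring = _LOCATION_DATES[location]
        rows.append(
            {
                "image_path": str(img_path),
                "image_id": image_id,
                "location": location,
                "planting_date": planting,
                "measuring_date": measuring,
                "difficulty": difficulty,
                "mask_path": str(mask_path),
            }
        )
    manifest = pd.DataFrame(rows)
    manifest.to_csv(out_dir / "manifest.csv", index=False)
    return manifest
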