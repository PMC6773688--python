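"""Batch feature extraction: images in, rectangular feature table out.

Per image the pipeline runs contrast stretch → segmentation → the
35-transform bank → 140 color + 315 texture features, and appends the two
covariates Location (site code 1–4) and Time (days from planting to
measurement).  The resulting table has 457 predictor columns; the reduced
view keeps only the raw-channel features plus the covariates
(12 color + 27 texture + 2 = 41 columns).

Images whose mask cleans to empty (or any other per-image failure) are
retained as rows flagged ``valid = False`` with the failure reason, so
availability gaps stay auditable.  Extraction is fully deterministic.
"""

from __future__ import annotations

import datetime as dt
import json
import logging
from dataclasses import dataclass
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd

from . import __version__
from .color_features import all_color_features, color_feature_names
from .config import PipelineConfig
from .glcm import EmptyGlcmError, all_texture_features, texture_feature_names
from .preprocess import build_plant_mask, compute_seg_indices, stretch_contrast
from .transforms import transform_bank

__all__ = [
    "ImageMetadata",
    "compute_time",
    "feature_columns",
    "rgb_lnt_columns",
    "extract_features",
    "run_batch",
    "feature_correlation",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ImageMetadata:
    """Identity and covariate metadata for one image."""

    image_id: str
    location: int
    planting_date: dt.date
    measuring_date: dt.date


def compute_time(meta: ImageMetadata) -> int:
    """Days between planting and measuring (plain calendar difference)."""
    days = (meta.measuring_date - meta.planting_date).days
    if days < 0:
        raise ValueError(
            f"measuring date {meta.measuring_date} precedes planting date {meta.planting_date}"
        )
    return days


def feature_columns() -> list[str]:
    """The 457 predictor column names: 140 color, 315 texture, location, time."""
    return color_feature_names() + texture_feature_names() + ["location", "time"]


def rgb_lnt_columns() -> list[str]:
    """The 41-column reduced view: raw-channel features plus the covariates."""
    rgb = ("R", "G", "B")
    return color_feature_names(rgb) + texture_feature_names(rgb) + ["location", "time"]


def extract_features(
    image: np.ndarray,
    meta: ImageMetadata,
    config: PipelineConfig = PipelineConfig(),
) -> dict:
    """The full feature record for one RGB image.

    Returns a mapping with ``image_id``, the 455 image features, ``location``
    and ``time``, plus ``valid``/``reason`` flags.  An empty plant mask or an
    empty co-occurrence matrix yields ``valid = False`` with every feature
    NA, keeping the table rectangular.
    """
    record: dict = {"image_id": meta.image_id}
    record.update({c: np.nan for c in feature_columns()})
    record["location"] = meta.location
    record["time"] = compute_time(meta)
    record["valid"] = True
    record["reason"] = ""
    try:
        stretched = stretch_contrast(image)
        mask = build_plant_mask(
            compute_seg_indices(stretched),
            exg_threshold=config.exg_threshold,
            min_object_pixels=config.min_object_pixels,
            connectivity=config.connectivity,
        )
        if not mask.any():
            raise ValueError("plant mask is empty after cleaning")
        bank = transform_bank(stretched, mask, assume_linear_rgb=config.assume_linear_rgb)
        record.update(all_color_features(bank))
        record.update(
            all_texture_features(
                bank,
                mask,
                d=config.displacement,
                directions=config.directions,
                levels=config.gray_levels,
            )
        )
    except (ValueError, EmptyGlcmError) as exc:
        record["valid"] = False
        record["reason"] = str(exc)
    return record


def _parse_date(value) -> dt.date:
    if isinstance(value, dt.date):
        return value
    return dt.date.fromisoformat(str(value))


def run_batch(
    manifest: pd.DataFrame | str | Path,
    out_csv: str | Path | None = None,
    config: PipelineConfig = PipelineConfig(),
) -> pd.DataFrame:
    """Extract features for every image in a manifest.

    The manifest needs columns ``image_path, image_id, location,
    planting_date, measuring_date`` (ISO dates).  Unreadable images become
    invalid rows, not fatal errors.  If ``out_csv`` is given the table is
    written as CSV (NA spelled ``NA``, full precision) with a JSON sidecar
    recording the configuration and package version.
    """
    if not isinstance(manifest, pd.DataFrame):
        manifest = pd.read_csv(manifest)
    if len(manifest) == 0:
        raise ValueError("empty manifest")
    records = []
    for row in manifest.itertuples(index=False):
        meta = ImageMetadata(
            image_id=str(row.image_id),
            location=int(row.location),
            planting_date=_parse_date(row.planting_date),
            measuring_date=_parse_date(row.measuring_date),
        )
        try:
            image = iio.imread(row.image_path)
            if image.ndim == 3 and image.shape[2] == 4:
                image = image[..., :3]
            record = extract_features(image, meta, config=config)
        except Exception as exc:  # unreadable/corrupt files must not kill the batch
            logger.warning("failed to process %s: %s", row.image_path, exc)
            record = {"image_id": meta.image_id}
            record.update({c: np.nan for c in feature_columns()})
            record["location"] = meta.location
            record["time"] = compute_time(meta)
            record["valid"] = False
            record["reason"] = str(exc)
        records.append(record)
    columns = ["image_id"] + feature_columns() + ["valid", "reason"]
    table = pd.DataFrame.from_records(records, columns=columns)
    if out_csv is not None:
        out_csv = Path(out_csv)
        out_csv.parent.mkdir(parents=True, exist_ok=True)
        table.to_csv(out_csv, index=False, na_rep="NA", float_format="%.17g")
        sidecar = {"version": __version__, "config": config.to_dict(), "n_images": len(table)}
        out_csv.with_suffix(".config.json").write_text(json.dumps(sidecar, indent=2))
    return table


def feature_correlation(table: pd.DataFrame) -> pd.DataFrame:
    """Pearson correlation matrix of the 455 image-derived feature columns.

    Uses valid rows only; constant columns get NA correlations (pairwise).
    Requires at least 3 valid rows.
    """
    cols = color_feature_names() + texture_feature_names()
    valid = table[table["valid"].astype(bool)] if "valid" in table else table
    if len(valid) < 3:
        raise ValueError(f"need at least 3 valid rows, got {len(valid)}")
    return valid[cols].astype(float).corr(method="pearson")
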