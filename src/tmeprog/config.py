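"""Configuration objects holding every tunable constant of the pipeline.

All image-processing window sizes, HSV gates and calibration constants default
to the values used by the published stroma/CD8 quantification protocol; they
are collected here so a single TOML file can override any of them.
"""

from __future__ import annotations

import dataclasses
import tomllib
from dataclasses import dataclass, field
from pathlib import Path


@dataclass(frozen=True)
class StromaConfig:
    """Constants of the H&E stroma-fraction pipeline.

    Window sizes are in pixels and odd; HSV saturation/value gates live on
    [0, 1]; ``cf1``/``cf2`` are the scanner calibration offset and slope
    (defaults are the Aperio AT2 constants).
    """

    mean_filter_size: int = 7
    median_filter_size: int = 9
    sd_filter_size: int = 17
    closing_size: int = 5
    min_region_px: int = 200
    otsu_scale: float = 1.15
    value_min: float = 0.2
    saturation_min: float = 0.4
    grey_weights: tuple[float, float, float] = (0.3, 0.6, 0.1)
    white_percentile: float = 95.0
    white_target: float = 240.0
    rescale_low_pct: float = 1.0
    rescale_high_pct: float = 99.0
    # Huo-style iterative white balance (grey-point extraction in YUV)
    wb_grey_chroma_ratio: float = 0.15
    wb_min_luma_frac: float = 0.7  # of the tile's 95th luma percentile
    wb_max_iter: int = 16
    wb_tol: float = 0.5
    wb_saturation_cut: int = 254
    # stain-vector estimation
    od_floor: float = 0.15
    min_tissue_px: int = 500
    angle_low_pct: float = 1.0
    angle_high_pct: float = 99.0
    cf1: float = 0.037
    cf2: float = 0.9852


@dataclass(frozen=True)
class IhcConfig:
    """Constants of the CD8 IHC core quantifier.

    Hue intervals are in degrees on [0, 360); DAB brown counts as positive,
    hematoxylin blue as negative.  Cores with fewer than ``min_cells_qc``
    detected nuclei fail quality control and are excluded from patient means.
    """

    radius_min: int = 4
    radius_max: int = 12
    sensitivity: float = 0.45
    positive_hue: tuple[float, float] = (10.0, 50.0)
    negative_hue: tuple[float, float] = (180.0, 280.0)
    sat_min: float = 0.15
    value_min: float = 0.15
    value_max: float = 0.95
    min_cells_qc: int = 1000


@dataclass(frozen=True)
class GridConfig:
    """Threshold-grid resolution for the combined-marker cutpoint search."""

    cd8_step: float = 0.001
    stroma_step: float = 0.01
    min_group_size: int = 5

    def __post_init__(self) -> None:
        if self.cd8_step <= 0 or self.stroma_step <= 0:
            raise ValueError("grid steps must be positive")
        if self.min_group_size < 1:
            raise ValueError("min_group_size must be >= 1")


def _from_mapping(cls, mapping: dict):
    names = {f.name for f in dataclasses.fields(cls)}
    unknown = set(mapping) - names
    if unknown:
        raise KeyError(f"unknown {cls.__name__} keys: {sorted(unknown)}")
    coerced = {
        k: tuple(v) if isinstance(v, list) else v for k, v in mapping.items()
    }
    return cls(**coerced)


def load_config(path: str | Path):
    """Read a TOML config file with optional [stroma], [ihc], [grid] tables.

    Returns a ``(StromaConfig, IhcConfig, GridConfig)`` triple with file
    values overriding the defaults.
    """
    with open(path, "rb") as fh:
        raw = tomllib.load(fh)
    stroma = _from_mapping(StromaConfig, raw.get("stroma", {}))
    ihc = _from_mapping(IhcConfig, raw.get("ihc", {}))
    grid = _from_mapping(GridConfig, raw.get("grid", {}))
    return stroma, ihc, grid
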