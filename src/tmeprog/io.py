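"""Reading and writing tiles, masks and detection tables."""

from __future__ import annotations

from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd

from .stroma import RgbTile


def read_tile(path: str | Path, annotation_path: str | Path | None = None) -> RgbTile:
    """Load an RGB PNG/TIFF tile, optionally with a mask PNG annotation.

    Annotation pixels >= 128 count as inside the annotated tumor region.
    """
    pixels = np.asarray(iio.imread(path))
    if pixels.ndim == 2:
        pixels = np.stack([pixels] * 3, axis=-1)
    if pixels.shape[2] == 4:
        pixels = pixels[..., :3]
    annotation = None
    if annotation_path is not None:
        ann = np.asarray(iio.imread(annotation_path))
        if ann.ndim == 3:
            ann = ann[..., 0]
        annotation = ann >= 128
    return RgbTile(pixels.astype(np.uint8), annotation)


def write_tile(path: str | Path, tile: RgbTile) -> None:
    iio.imwrite(path, tile.pixels)


def write_mask(path: str | Path, mask: np.ndarray) -> None:
    """Write a mask PNG; boolean masks map to 0/255, uint8 pass through."""
    arr = np.asarray(mask)
    if arr.dtype == bool:
        arr = arr.astype(np.uint8) * 255
    iio.imwrite(path, arr.astype(np.uint8))


def write_detections(path: str | Path, detections: pd.DataFrame) -> None:
    detections.to_csv(path, index=False)


def read_cohort(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path)
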