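"""CD8+ T-lymphocyte quantification on IHC tissue cores.

Nuclei are detected with a gradient-based circular Hough transform and
classified as positive (DAB brown) or negative (hematoxylin blue) by HSV
thresholds on the median color inside each detected disk.  The core-level
CD8+ fraction is positive / total nuclei; cores with fewer than 1000
detected cells fail quality control, and the per-patient value is the mean
fraction over QC-passing replicate cores.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from skimage.color import rgb2hsv
from skimage.feature import canny
from skimage.transform import hough_circle, hough_circle_peaks

from .config import IhcConfig
from .stroma import RgbTile, grey_convert


@dataclass(frozen=True)
class NucleusDetection:
    center_row: float
    center_col: float
    radius: float
    label: str  # 'positive' | 'negative'

    def __post_init__(self) -> None:
        if self.radius <= 0:
            raise ValueError("radius must be positive")


@dataclass
class IhcCoreResult:
    detections: list
    n_positive: int
    n_total: int
    fraction: float | None
    passed_qc: bool


@dataclass
class PatientCd8:
    core_results: list
    mean_fraction: float | None
    missing: bool = False


def detect_nuclei(
    core_tile: RgbTile | np.ndarray,
    radius_range: tuple[int, int] = (4, 12),
    sensitivity: float = 0.45,
) -> list[tuple[tuple[int, int], int]]:
    """Circular-Hough nucleus detection.

    Edges come from a Canny detector on the grey image; accumulators are
    normalized per radius, peaks below ``sensitivity`` are dropped, and
    non-maximum suppression keeps detections at least the minimum radius
    apart.  Returns ``[((row, col), radius), ...]``; an empty list when
    nothing is found.
    """
    rmin, rmax = radius_range
    if rmin <= 0 or rmin > rmax:
        raise ValueError("invalid radius range")
    pixels = core_tile.pixels if isinstance(core_tile, RgbTile) else core_tile
    grey = grey_convert(pixels) / 255.0
    edges = canny(grey, sigma=1.0)
    if not edges.any():
        return []
    radii = np.arange(rmin, rmax + 1)
    accum = hough_circle(edges, radii)
    n_max = int(edges.sum())  # generous cap; threshold does the real pruning
    _, cx, cy, rr = hough_circle_peaks(
        accum,
        radii,
        min_xdistance=rmin,
        min_ydistance=rmin,
        threshold=sensitivity,
        total_num_peaks=n_max,
    )
    return [((int(y), int(x)), int(r)) for x, y, r in zip(cx, cy, rr)]


def _disk_median_hsv(pixels: np.ndarray, row: int, col: int, radius: float):
    h, w = pixels.shape[:2]
    r_i = int(radius)
    y0, y1 = max(0, row - r_i), min(h, row + r_i + 1)
    x0, x1 = max(0, col - r_i), min(w, col + r_i + 1)
    yy, xx = np.ogrid[y0 - row : y1 - row, x0 - col : x1 - col]
    inside = yy * yy + xx * xx <= radius * radius
    patch = pixels[y0:y1, x0:x1][inside]
    if patch.size == 0:
        return None
    hsv = rgb2hsv(patch.reshape(1, -1, 3).astype(float) / 255.0).reshape(-1, 3)
    med = np.median(hsv, axis=0)
    return med[0] * 360.0, med[1], med[2]


def classify_nucleus(
    core_tile: RgbTile | np.ndarray,
    detection: tuple[tuple[int, int], float],
    config: IhcConfig = IhcConfig(),
) -> str | None:
    """Label a detected nucleus by the median HSV over its disk interior.

    Returns 'positive' (brown), 'negative' (blue), or None when the color
    matches neither range (such nuclei are discarded from all counts).
    """
    pixels = core_tile.pixels if isinstance(core_tile, RgbTile) else core_tile
    (row, col), radius = detection
    hsv = _disk_median_hsv(np.asarray(pixels), int(row), int(col), radius)
    if hsv is None:
        return None
    hue, sat, val = hsv
    if sat < config.sat_min or not (config.value_min <= val <= config.value_max):
        return None
    if config.positive_hue[0] <= hue <= config.positive_hue[1]:
        return "positive"
    if config.negative_hue[0] <= hue <= config.negative_hue[1]:
        return "negative"
    return None


def quantify_core(core_tile: RgbTile | np.ndarray, config: IhcConfig = IhcConfig()) -> IhcCoreResult:
    """Detect, classify and count nuclei in one core."""
    raw = detect_nuclei(
        core_tile, (config.radius_min, config.radius_max), config.sensitivity
    )
    detections: list[NucleusDetection] = []
    for (row, col), radius in raw:
        label = classify_nucleus(core_tile, ((row, col), radius), config)
        if label is None:
            continue
        detections.append(NucleusDetection(row, col, radius, label))
    n_pos = sum(1 for d in detections if d.label == "positive")
    n_total = len(detections)
    fraction = n_pos / n_total if n_total > 0 else None
    return IhcCoreResult(
        detections=detections,
        n_positive=n_pos,
        n_total=n_total,
        fraction=fraction,
        passed_qc=n_total >= config.min_cells_qc,
    )


def patient_mean_fraction(core_results: list[IhcCoreResult]) -> PatientCd8:
    """Average the core fractions over QC-passing cores only.

    A patient whose cores all fail QC is flagged missing and excluded from
    downstream analyses.
    """
    passing = [c for c in core_results if c.passed_qc and c.fraction is not None]
    if not passing:
        return PatientCd8(core_results=core_results, mean_fraction=None, missing=True)
    mean = float(np.mean([c.fraction for c in passing]))
    return PatientCd8(core_results=core_results, mean_fraction=mean, missing=False)
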