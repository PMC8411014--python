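"""Tumor-stroma fraction estimation from annotated H&E tiles.

The pipeline mirrors the automated stroma analyzer used for whole-slide
tumor-stroma ratio scoring in colorectal cancer:

1. iterative grey-point white balance in YUV space,
2. global rescale so the 95th grey-level percentile maps to 240,
3. automatic stain-vector estimation and color deconvolution into a
   hematoxylin image and a combined H&E image,
4. a tissue-foreground mask from the mean-filtered H&E image (HSV gates),
5. a stroma/epithelium mask from median- and SD-filtered hematoxylin
   grey levels, Otsu thresholding (scaled by 1.15), small-region removal
   and morphological closing,
6. stroma fraction = stroma px / (stroma px + epithelium px) inside the
   pathologist annotation, followed by an affine scanner calibration
   ``(fraction - cf1) / cf2``.

All array-level operations accept plain ``HxWx3`` arrays (uint8 or float on
the 0-255 scale) so they compose freely; :func:`quantify_tile` wires the
whole chain together for an :class:`RgbTile`.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage, stats
from skimage.color import rgb2hsv
from skimage.morphology import closing as _grey_closing

from .config import StromaConfig

# Reference H&E optical-density unit vectors (Ruifrok-style), used as the
# fallback when automatic stain estimation finds a degenerate stain plane.
REFERENCE_HEMATOXYLIN = np.array([0.65, 0.70, 0.29])
REFERENCE_EOSIN = np.array([0.07, 0.99, 0.11])
REFERENCE_HEMATOXYLIN = REFERENCE_HEMATOXYLIN / np.linalg.norm(REFERENCE_HEMATOXYLIN)
REFERENCE_EOSIN = REFERENCE_EOSIN / np.linalg.norm(REFERENCE_EOSIN)


class DegenerateInputError(ValueError):
    """Raised when an image or value grid carries no usable information."""


@dataclass
class RgbTile:
    """An 8-bit RGB tile with an optional aligned tumor-annotation mask."""

    pixels: np.ndarray
    annotation: np.ndarray | None = None

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels)
        if px.ndim != 3 or px.shape[2] != 3:
            raise ValueError("pixels must be an HxWx3 array")
        if px.min() < 0 or px.max() > 255:
            raise ValueError("channel values must lie in [0, 255]")
        self.pixels = px
        if self.annotation is not None:
            ann = np.asarray(self.annotation).astype(bool)
            if ann.shape != px.shape[:2]:
                raise ValueError("annotation must match tile height/width")
            self.annotation = ann

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape[:2]


@dataclass(frozen=True)
class StainVectors:
    """Unit optical-density vectors of the two stains."""

    v_hematoxylin: np.ndarray
    v_eosin: np.ndarray
    fallback: bool = False

    def __post_init__(self) -> None:
        for v in (self.v_hematoxylin, self.v_eosin):
            if not np.isclose(np.linalg.norm(v), 1.0, atol=1e-6):
                raise ValueError("stain vectors must be unit norm")
            if np.any(np.asarray(v) < -1e-9):
                raise ValueError("stain vectors must be non-negative")
        cosang = float(np.dot(self.v_hematoxylin, self.v_eosin))
        if cosang > 1 - 1e-9:
            raise ValueError("stain vectors must not be collinear")

    def basis(self) -> np.ndarray:
        """3x2 matrix with the stain vectors as columns."""
        return np.stack([self.v_hematoxylin, self.v_eosin], axis=1)


@dataclass(frozen=True)
class CalibrationPair:
    """Affine scanner calibration: corrected = (raw - cf1) / cf2."""

    cf1: float
    cf2: float
    scanner_label: str = ""

    def __post_init__(self) -> None:
        if self.cf2 == 0:
            raise ValueError("cf2 must be non-zero")


APERIO_AT2 = CalibrationPair(cf1=0.037, cf2=0.9852, scanner_label="Aperio AT2")
IDENTITY_CALIBRATION = CalibrationPair(cf1=0.0, cf2=1.0, scanner_label="identity")


@dataclass
class StromaResult:
    """Output of the tile-level stroma quantification."""

    raw_fraction: float
    corrected_fraction: float
    cf1: float
    cf2: float
    stroma_area_px: int
    epithelium_area_px: int
    foreground_mask: np.ndarray
    stroma_mask: np.ndarray
    final_mask: np.ndarray
    flags: dict = field(default_factory=dict)


def _as_float(img: np.ndarray) -> np.ndarray:
    return np.asarray(img, dtype=float)


def grey_convert(image: np.ndarray, weights=(0.3, 0.6, 0.1)) -> np.ndarray:
    """Weighted RGB-to-grey conversion (default weights 0.3 R, 0.6 G, 0.1 B)."""
    img = _as_float(image)
    w = np.asarray(weights, dtype=float)
    return img @ w


def white_balance(
    tile: RgbTile, config: StromaConfig = StromaConfig()
) -> tuple[RgbTile, bool]:
    """Iterative grey-point white balance in YUV space.

    Grey candidates are bright pixels (luma above ``wb_min_luma_frac`` times
    the tile's 95th luma percentile, not fully saturated) whose
    chroma-to-luma ratio (|U|+|V|)/Y falls below
    ``wb_grey_chroma_ratio``.  Each
    iteration rescales the R and B channels so the candidate means match the
    candidate luma; iteration stops when the mean chroma magnitude drops
    below ``wb_tol`` or after ``wb_max_iter`` rounds.

    Returns the balanced tile and a warning flag that is set when no grey
    candidates exist (tile returned unchanged).
    """
    img = _as_float(tile.pixels)
    gains = np.ones(3)
    warned = False
    for _ in range(config.wb_max_iter):
        cur = img * gains
        r, g, b = cur[..., 0], cur[..., 1], cur[..., 2]
        y = 0.299 * r + 0.587 * g + 0.114 * b
        u = 0.492 * (b - y)
        v = 0.877 * (r - y)
        unsaturated = ~np.all(img >= config.wb_saturation_cut, axis=-1)
        with np.errstate(divide="ignore", invalid="ignore"):
            chroma_ratio = (np.abs(u) + np.abs(v)) / np.where(y > 0, y, np.inf)
        luma_floor = config.wb_min_luma_frac * float(np.percentile(y, 95))
        cand = (
            unsaturated
            & (y >= luma_floor)
            & (y > 0)
            & (chroma_ratio <= config.wb_grey_chroma_ratio)
        )
        if not cand.any():
            warned = True
            break
        mu, mv = float(u[cand].mean()), float(v[cand].mean())
        if abs(mu) <= config.wb_tol and abs(mv) <= config.wb_tol:
            break
        y_mean = float(y[cand].mean())
        b_mean = float(b[cand].mean())
        r_mean = float(r[cand].mean())
        if b_mean > 0:
            gains[2] *= y_mean / b_mean
        if r_mean > 0:
            gains[0] *= y_mean / r_mean
    if warned or np.allclose(gains, 1.0):
        return RgbTile(tile.pixels.copy(), tile.annotation), warned
    out = np.clip(np.rint(img * gains), 0, 255).astype(np.uint8)
    return RgbTile(out, tile.annotation), warned


def rescale_to_reference_white(
    tile: RgbTile, config: StromaConfig = StromaConfig()
) -> RgbTile:
    """Scale all channels so the 95th grey-level percentile maps to 240."""
    grey = grey_convert(tile.pixels, config.grey_weights)
    p95 = float(np.percentile(grey, config.white_percentile))
    if p95 <= 0:
        raise DegenerateInputError("grey 95th percentile is zero (black tile)")
    factor = config.white_target / p95
    out = np.clip(np.rint(_as_float(tile.pixels) * factor), 0, 255).astype(np.uint8)
    return RgbTile(out, tile.annotation)


def optical_density(image: np.ndarray, background: float = 255.0) -> np.ndarray:
    """Beer-Lambert optical density, OD = -ln(I / I0), with I floored at 1."""
    img = np.maximum(_as_float(image), 1.0)
    return -np.log(img / background)


def estimate_stain_vectors(
    tile: RgbTile | np.ndarray, config: StromaConfig = StromaConfig()
) -> StainVectors:
    """Automatic stain-vector estimation by a plane fit in OD space.

    Tissue pixels (all OD channels above ``od_floor``) are projected onto
    the dominant two-dimensional stain plane (SVD); the extreme directions
    at robust angular percentiles are taken as the stain vectors.  The
    hematoxylin vector is the one with the larger blue OD component.  Tiles
    with too few tissue pixels or a collapsed stain plane fall back to
    published reference H&E vectors (``fallback=True``).
    """
    pixels = tile.pixels if isinstance(tile, RgbTile) else tile
    od = optical_density(pixels).reshape(-1, 3)
    tissue = od[np.linalg.norm(od, axis=1) > config.od_floor]
    if tissue.shape[0] < config.min_tissue_px:
        return StainVectors(REFERENCE_HEMATOXYLIN, REFERENCE_EOSIN, fallback=True)
    _, svals, vt = np.linalg.svd(tissue, full_matrices=False)
    if svals[1] < 1e-4 * svals[0]:
        return StainVectors(REFERENCE_HEMATOXYLIN, REFERENCE_EOSIN, fallback=True)
    plane = vt[:2]
    # orient basis so projections land in the positive half-plane
    if plane[0] @ tissue.mean(axis=0) < 0:
        plane = plane * np.array([[-1.0], [1.0]])
    coords = tissue @ plane.T
    angles = np.arctan2(coords[:, 1], coords[:, 0])
    lo = np.percentile(angles, config.angle_low_pct)
    hi = np.percentile(angles, config.angle_high_pct)
    if hi - lo < np.deg2rad(2.0):
        return StainVectors(REFERENCE_HEMATOXYLIN, REFERENCE_EOSIN, fallback=True)
    vecs = []
    for ang in (lo, hi):
        v = np.cos(ang) * plane[0] + np.sin(ang) * plane[1]
        if v.sum() < 0:
            v = -v
        v = np.clip(v, 0.0, None)
        vecs.append(v / np.linalg.norm(v))
    # hematoxylin absorbs less blue light than eosin: larger blue OD share
    if vecs[0][2] >= vecs[1][2]:
        v_h, v_e = vecs
    else:
        v_e, v_h = vecs
    return StainVectors(v_h, v_e, fallback=False)


def color_deconvolve(
    image: RgbTile | np.ndarray, vectors: StainVectors
) -> tuple[np.ndarray, np.ndarray]:
    """Unmix an RGB image into hematoxylin-only and combined H&E renderings.

    Per-pixel OD is projected onto the stain basis (least squares), negative
    concentrations are clamped to zero, and each output is re-rendered to
    RGB via Beer-Lambert with the corresponding vector(s).  Returns float
    arrays on the 0-255 scale.
    """
    pixels = image.pixels if isinstance(image, RgbTile) else image
    basis = vectors.basis()
    if abs(np.linalg.det(basis.T @ basis)) < 1e-12:
        raise ValueError("singular stain basis")
    od = optical_density(pixels)
    shape = od.shape[:2]
    conc = np.linalg.lstsq(basis, od.reshape(-1, 3).T, rcond=None)[0]
    conc = np.clip(conc, 0.0, None)
    c_h, c_e = conc[0].reshape(shape), conc[1].reshape(shape)
    h_img = 255.0 * np.exp(-c_h[..., None] * vectors.v_hematoxylin)
    he_od = c_h[..., None] * vectors.v_hematoxylin + c_e[..., None] * vectors.v_eosin
    he_img = 255.0 * np.exp(-he_od)
    return h_img, he_img


def compute_foreground_mask(
    combined_he_image: np.ndarray, config: StromaConfig = StromaConfig()
) -> np.ndarray:
    """Tissue-foreground mask from the mean-filtered combined H&E image.

    A 7x7 averaging filter is applied per RGB channel; the result is
    converted to HSV and pixels with V >= 0.2 and S >= 0.4 (inclusive) are
    foreground.
    """
    img = _as_float(combined_he_image)
    size = config.mean_filter_size
    smooth = np.stack(
        [ndimage.uniform_filter(img[..., c], size=size, mode="reflect") for c in range(3)],
        axis=-1,
    )
    hsv = rgb2hsv(np.clip(smooth, 0, 255) / 255.0)
    return (hsv[..., 2] >= config.value_min) & (hsv[..., 1] >= config.saturation_min)


def percentile_rescale(
    grid: np.ndarray, low_pct: float = 1.0, high_pct: float = 99.0
) -> tuple[np.ndarray, bool]:
    """Linear stretch mapping the 1st percentile to 0 and the 99th to 255.

    Values outside the percentile window are clipped.  A constant grid (equal
    percentiles) is degenerate: all pixels map to 0 and the flag is set.
    """
    g = _as_float(grid)
    if g.size == 0:
        raise DegenerateInputError("empty grid")
    p_lo = float(np.percentile(g, low_pct))
    p_hi = float(np.percentile(g, high_pct))
    if p_hi <= p_lo:
        return np.zeros_like(g), True
    out = np.clip((g - p_lo) * 255.0 / (p_hi - p_lo), 0.0, 255.0)
    return out, False


def sample_sd_filter(grid: np.ndarray, size: int) -> np.ndarray:
    """Moving sample standard deviation (n-1 denominator), reflect padding."""
    g = _as_float(grid)
    n = size * size
    m = ndimage.uniform_filter(g, size=size, mode="reflect")
    m2 = ndimage.uniform_filter(g * g, size=size, mode="reflect")
    var = (m2 - m * m) * (n / (n - 1))
    return np.sqrt(np.clip(var, 0.0, None))


def otsu_threshold(grid: np.ndarray) -> int:
    """Otsu's method over all 256 8-bit levels.

    Pixels are binned to the nearest integer level; the returned threshold t
    minimizes the weighted within-class variance of the classes {v <= t} and
    {v > t}, with ties broken toward the lower level.
    """
    levels = np.clip(np.rint(_as_float(grid)), 0, 255).astype(np.int64).ravel()
    if np.unique(levels).size < 2:
        raise DegenerateInputError("constant grid has no Otsu threshold")
    hist = np.bincount(levels, minlength=256).astype(float)
    total = hist.sum()
    vals = np.arange(256, dtype=float)
    w0 = np.cumsum(hist)
    sum0 = np.cumsum(hist * vals)
    sumsq0 = np.cumsum(hist * vals * vals)
    w1 = total - w0
    sum1 = sum0[-1] - sum0
    sumsq1 = sumsq0[-1] - sumsq0
    with np.errstate(divide="ignore", invalid="ignore"):
        var0 = sumsq0 - sum0 * sum0 / np.where(w0 > 0, w0, np.inf)
        var1 = sumsq1 - sum1 * sum1 / np.where(w1 > 0, w1, np.inf)
    within = np.where((w0 > 0) & (w1 > 0), var0 + var1, np.inf)[:255]
    return int(np.argmin(within))  # argmin takes the first (lowest) minimizer


def remove_small_regions(mask: np.ndarray, min_px: int) -> np.ndarray:
    """Drop 8-connected components with fewer than ``min_px`` pixels."""
    m = np.asarray(mask, bool)
    labels, n = ndimage.label(m, structure=np.ones((3, 3), int))
    if n == 0:
        return m.copy()
    sizes = np.bincount(labels.ravel())
    keep = sizes >= min_px
    keep[0] = False
    return keep[labels]


def compute_stroma_mask(
    hematoxylin_image: np.ndarray, config: StromaConfig = StromaConfig()
) -> tuple[np.ndarray, bool]:
    """Stroma/epithelium mask from the normalized hematoxylin image.

    Grey conversion -> 9x9 median filter -> 17x17 sample-SD filter of the
    median image; both intermediate images are percentile-rescaled to 0-255,
    averaged (the SD component inverted so both increase with stroma
    likelihood), thresholded at 1.15x the Otsu level, cleaned of 8-connected
    regions below 200 pixels and closed with a 5x5 structuring element.

    Returns ``(mask, degenerate)``; degenerate is set (empty mask) when both
    percentile stretches collapse.
    """
    grey = grey_convert(hematoxylin_image, config.grey_weights)
    med = ndimage.median_filter(grey, size=config.median_filter_size, mode="reflect")
    sd = sample_sd_filter(med, config.sd_filter_size)
    med_r, deg_med = percentile_rescale(med, config.rescale_low_pct, config.rescale_high_pct)
    sd_r, deg_sd = percentile_rescale(sd, config.rescale_low_pct, config.rescale_high_pct)
    if deg_med and deg_sd:
        return np.zeros(grey.shape, bool), True
    # stroma is hematoxylin-poor (bright median) and texture-poor (low SD)
    combined = (med_r + (255.0 - sd_r)) / 2.0
    try:
        level = otsu_threshold(combined)
    except DegenerateInputError:
        return np.zeros(grey.shape, bool), True
    mask = combined > level * config.otsu_scale
    mask = remove_small_regions(mask, config.min_region_px)
    mask = _grey_closing(mask, footprint=np.ones((config.closing_size,) * 2, bool))
    return mask.astype(bool), False


def combine_masks(
    stroma_mask: np.ndarray,
    foreground_mask: np.ndarray,
    annotation: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Intersect the stroma mask with tissue foreground and the annotation.

    Returns ``(final_stroma_mask, epithelium_mask)``: epithelium is the
    non-stroma tissue inside foreground AND annotation.
    """
    s = np.asarray(stroma_mask, bool)
    f = np.asarray(foreground_mask, bool)
    if annotation is None:
        annotation = np.ones_like(s)
    a = np.asarray(annotation, bool)
    if not (s.shape == f.shape == a.shape):
        raise ValueError("mask dimensions differ")
    final = s & f & a
    epithelium = (~s) & f & a
    return final, epithelium


def stroma_fraction(final_mask: np.ndarray, epithelium_mask: np.ndarray) -> float:
    """Stroma pixels over combined stroma + epithelium pixels."""
    s = int(np.count_nonzero(final_mask))
    e = int(np.count_nonzero(epithelium_mask))
    if s + e == 0:
        raise DegenerateInputError("no tissue pixels")
    return s / (s + e)


def calibrate_fraction(raw_fraction: float, calibration: CalibrationPair) -> float:
    """Apply the affine scanner calibration (raw - cf1) / cf2, unclamped."""
    if calibration.cf2 == 0:
        raise ValueError("cf2 must be non-zero")
    return (raw_fraction - calibration.cf1) / calibration.cf2


def estimate_calibration(
    paired_fractions, scanner_label: str = ""
) -> CalibrationPair:
    """Least-squares calibration from fractions measured on two scanners.

    ``paired_fractions`` is a sequence of (reference_fraction, raw_fraction)
    pairs; ordinary least squares of the second on the first yields the
    intercept cf1 and slope cf2 such that (raw - cf1)/cf2 recovers the
    reference scale.
    """
    pairs = np.asarray(list(paired_fractions), dtype=float)
    if pairs.ndim != 2 or pairs.shape[1] != 2 or pairs.shape[0] < 3:
        raise ValueError("need at least 3 (reference, raw) pairs")
    a, b = pairs[:, 0], pairs[:, 1]
    if np.ptp(a) == 0:
        raise ValueError("constant predictor; cannot regress")
    fit = stats.linregress(a, b)
    return CalibrationPair(cf1=float(fit.intercept), cf2=float(fit.slope),
                           scanner_label=scanner_label)


def quantify_tile(
    tile: RgbTile,
    config: StromaConfig = StromaConfig(),
    calibration: CalibrationPair | None = None,
) -> StromaResult:
    """Run the full stroma pipeline on one annotated tile."""
    calibration = calibration or CalibrationPair(config.cf1, config.cf2)
    flags: dict = {}
    balanced, wb_warn = white_balance(tile, config)
    flags["white_balance_warning"] = wb_warn
    normed = rescale_to_reference_white(balanced, config)
    vectors = estimate_stain_vectors(normed, config)
    flags["stain_fallback"] = vectors.fallback
    h_img, he_img = color_deconvolve(normed, vectors)
    foreground = compute_foreground_mask(he_img, config)
    stroma_mask, degenerate = compute_stroma_mask(h_img, config)
    flags["stroma_mask_degenerate"] = degenerate
    final, epithelium = combine_masks(stroma_mask, foreground, tile.annotation)
    raw = stroma_fraction(final, epithelium)
    corrected = calibrate_fraction(raw, calibration)
    flags["corrected_out_of_range"] = not (0.0 <= corrected <= 1.0)
    return StromaResult(
        raw_fraction=raw,
        corrected_fraction=corrected,
        cf1=calibration.cf1,
        cf2=calibration.cf2,
        stroma_area_px=int(np.count_nonzero(final)),
        epithelium_area_px=int(np.count_nonzero(epithelium)),
        foreground_mask=foreground,
        stroma_mask=stroma_mask,
        final_mask=final,
        flags=flags,
    )
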