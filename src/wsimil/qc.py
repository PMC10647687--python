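"""Tissue masking and per-tile quality control.

Background is separated from tissue by Otsu's threshold on the grayscale
thumbnail (tissue is the darker class on an H&E slide's bright background),
cleaned up morphologically, and the same slide-level threshold is re-applied
per tile together with a red-cutoff blood filter.  A tile survives QC only if
strictly more than 75 % of its pixels are neither background nor blood.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from skimage.morphology import closing, disk, opening, remove_small_holes, remove_small_objects

import shapely

from .datatypes import DegenerateHistogramError, TileQC, TileRef, TissueMask
from .slides import RoiSet

__all__ = [
    "QCParams",
    "otsu_threshold",
    "grayscale_u8",
    "build_tissue_mask",
    "classify_blood_pixels",
    "tile_keep_decision",
]

#: strict lower bound on the tissue fraction for a tile to be kept
TISSUE_FRACTION_CUTOFF = 0.75


@dataclass(frozen=True)
class QCParams:
    """Tunable QC parameters.

    ``red_cutoff``/``red_margin``: a pixel is blood iff R > red_cutoff and
    both R-G and R-B exceed red_margin (selects saturated red, spares eosin
    pink).  ``radius_thumb``/``radius_tile``: disk radii for morphological
    opening-then-closing at thumbnail and tile scale.  ``min_area``: connected
    fragments and holes below this pixel area are removed/filled.
    """

    red_cutoff: int = 170
    red_margin: int = 50
    radius_thumb: int = 2
    radius_tile: int = 3
    min_area: int = 64
    tissue_cutoff: float = TISSUE_FRACTION_CUTOFF


def otsu_threshold(histogram: np.ndarray) -> int:
    """Otsu's threshold from a 256-bin grayscale histogram.

    Returns the t in [0, 255] maximizing the between-class variance of the
    split {grey <= t} vs {grey > t}; on a plateau of maximizers the smallest
    t is returned.  Raises :class:`DegenerateHistogramError` when all pixels
    share one value (every split leaves a class empty).
    """
    hist = np.asarray(histogram, dtype=np.float64)
    if hist.shape != (256,):
        raise ValueError("histogram must have 256 bins")
    total = hist.sum()
    if total <= 0:
        raise ValueError("histogram is empty")
    if np.count_nonzero(hist) < 2:
        raise DegenerateHistogramError("all pixels share one grey value")
    p = hist / total
    levels = np.arange(256, dtype=np.float64)
    w0 = np.cumsum(p)                  # P(grey <= t)
    mu = np.cumsum(p * levels)         # E[grey * 1(grey <= t)]
    mu_total = mu[-1]
    w1 = 1.0 - w0
    with np.errstate(divide="ignore", invalid="ignore"):
        sigma_b = (mu_total * w0 - mu) ** 2 / (w0 * w1)
    sigma_b[~np.isfinite(sigma_b)] = -np.inf
    return int(np.argmax(sigma_b))     # argmax returns the first maximizer


def grayscale_u8(rgb: np.ndarray) -> np.ndarray:
    """ITU-R 601 luma of an 8-bit RGB image, rounded back to uint8."""
    rgb = np.asarray(rgb)
    if rgb.ndim == 2:
        return rgb.astype(np.uint8)
    y = rgb[..., 0] * 0.299 + rgb[..., 1] * 0.587 + rgb[..., 2] * 0.114
    return np.round(y).astype(np.uint8)


def _cleanup(mask: np.ndarray, radius: int, min_area: int) -> np.ndarray:
    """Opening then closing with a disk, drop small fragments, fill small holes."""
    footprint = disk(radius)
    out = closing(opening(mask, footprint), footprint)
    # drop fragments / fill holes with area < min_area (max_size is inclusive)
    out = remove_small_objects(out, max_size=min_area - 1)
    out = remove_small_holes(out, max_size=min_area - 1)
    return out


def build_tissue_mask(thumbnail: np.ndarray, slide_id: str = "", level: int = 0,
                      roi: RoiSet | None = None, roi_downsample: float = 1.0,
                      params: QCParams = QCParams()) -> TissueMask:
    """Slide-level tissue mask from a grayscale (or RGB) thumbnail.

    Pixels at or below the Otsu threshold are tissue candidates; the
    candidate mask is morphologically cleaned and, when an ROI is supplied,
    intersected with the rasterized ROI (``roi_downsample`` = level-0 pixels
    per thumbnail pixel).
    """
    gray = grayscale_u8(thumbnail)
    if gray.size == 0:
        raise ValueError("empty thumbnail")
    hist = np.bincount(gray.ravel(), minlength=256)[:256]
    t = otsu_threshold(hist)
    mask = _cleanup(gray <= t, params.radius_thumb, params.min_area)
    if roi is not None:
        mask &= _rasterize_roi(roi, gray.shape, roi_downsample)
    return TissueMask(slide_id=slide_id, level=level, mask=mask, otsu_threshold=t)


def _rasterize_roi(roi: RoiSet, shape: tuple[int, int], downsample: float) -> np.ndarray:
    h, w = shape
    ys, xs = np.mgrid[0:h, 0:w]
    # pixel centers mapped to the level-0 frame
    cx = (xs.ravel() + 0.5) * downsample
    cy = (ys.ravel() + 0.5) * downsample
    inside = shapely.contains_xy(roi.union, cx, cy)
    return inside.reshape(h, w)


def classify_blood_pixels(tile_rgb: np.ndarray, params: QCParams = QCParams()) -> np.ndarray:
    """Binary mask of blood pixels under the fixed red-cutoff rule."""
    rgb = np.asarray(tile_rgb).astype(np.int16)
    r, g, b = rgb[..., 0], rgb[..., 1], rgb[..., 2]
    return (r > params.red_cutoff) & (r - g > params.red_margin) & (r - b > params.red_margin)


def tile_keep_decision(tile_rgb: np.ndarray, slide_threshold: int,
                       tile: TileRef | None = None,
                       params: QCParams = QCParams()) -> TileQC:
    """Apply the slide's Otsu threshold, the blood filter and the >75 % rule.

    Order: threshold (tissue = grey <= slide threshold) -> blood classification
    -> morphological cleanup of the tissue-candidate mask at tile scale ->
    pixel counting.  ``tissue_frac`` counts pixels that are neither background
    nor blood; ``keep`` requires tissue_frac strictly above the cutoff.
    """
    gray = grayscale_u8(tile_rgb)
    blood = classify_blood_pixels(tile_rgb, params) if np.ndim(tile_rgb) == 3 \
        else np.zeros_like(gray, dtype=bool)
    candidates = _cleanup(gray <= slide_threshold, params.radius_tile, params.min_area)
    tissue = candidates & ~blood
    tissue_frac = float(tissue.mean())
    blood_frac = float(blood.mean())
    return TileQC(
        tile=tile,
        tissue_frac=tissue_frac,
        blood_frac=blood_frac,
        keep=tissue_frac > params.tissue_cutoff,
    )
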