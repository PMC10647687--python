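"""Pyramidal slide access, tile-grid enumeration and ROI handling.

Slides are generic tiled pyramidal TIFFs (level 0 first, factor-2
downsamples).  Level 0 is assumed to be the slide's base magnification
(40x-equivalent by default); 20x tiles cover a 512x512 level-0 window and are
read either from the pyramid level whose downsample is nearest 2, or by 2x
area-average downsampling of level-0 pixels when no such level exists.

Regions of interest arrive as GeoJSON polygons in level-0 pixel coordinates
(QuPath annotation exports parse as plain GeoJSON; feature properties are
ignored).
"""
from __future__ import annotations

import json
from dataclasses import dataclass
from functools import lru_cache
from pathlib import Path

import numpy as np
import shapely
import tifffile
from shapely.geometry import shape as shapely_shape
from shapely.geometry import MultiPolygon, Point, Polygon

from .datatypes import (
    DEFAULT_TILE_SIZE,
    MAG_SCALE,
    MAGNIFICATIONS,
    EmptyRoiError,
    MagnificationError,
    SlideReadError,
    SlideRef,
    TileRef,
)

__all__ = [
    "open_slide",
    "build_tile_grid",
    "read_tile",
    "read_level",
    "RoiSet",
    "load_roi",
    "tile_in_roi",
]


def open_slide(path: str | Path, slide_id: str | None = None,
               mpp_level0: float = 0.23, base_magnification: int = 40) -> SlideRef:
    """Open a pyramidal TIFF and return its :class:`SlideRef`.

    Raises :class:`SlideReadError` if the file is missing or unreadable.
    """
    path = Path(path)
    try:
        with tifffile.TiffFile(path) as tif:
            dims = []
            for page in tif.pages:
                h, w = page.shape[:2]
                dims.append((int(w), int(h)))
    except (FileNotFoundError, OSError, tifffile.TiffFileError) as exc:
        raise SlideReadError(f"cannot read slide {path}: {exc}") from exc
    if not dims:
        raise SlideReadError(f"no image levels in {path}")
    return SlideRef(
        slide_id=slide_id or path.stem,
        path=str(path),
        level_dims=tuple(dims),
        mpp_level0=mpp_level0,
        base_magnification=base_magnification,
    )


@lru_cache(maxsize=8)
def _load_level(path: str, level: int) -> np.ndarray:
    with tifffile.TiffFile(path) as tif:
        return tif.pages[level].asarray()


def read_level(slide: SlideRef, level: int) -> np.ndarray:
    """Full pixel array of one pyramid level (cached)."""
    return _load_level(slide.path, level)


def _mag_downsample(slide: SlideRef, magnification: str) -> int:
    """Level-0 pixels per tile pixel for the requested magnification."""
    if magnification not in MAG_SCALE:
        raise MagnificationError(f"unknown magnification {magnification!r}")
    factor = slide.base_magnification // {"40x": 40, "20x": 20}[magnification]
    if factor < 1 or slide.base_magnification % (40 if magnification == "40x" else 20):
        raise MagnificationError(
            f"{magnification} not derivable from a {slide.base_magnification}x slide")
    return factor


def build_tile_grid(slide: SlideRef, tile_size: int = DEFAULT_TILE_SIZE,
                    magnifications: tuple[str, ...] = MAGNIFICATIONS) -> list[TileRef]:
    """Enumerate the full non-overlapping tile grid per magnification.

    Windows are half-open ``[x, x+s) x [y, y+s)`` in the level-0 frame,
    origin top-left; partial edge tiles are excluded, so the grid has
    ``floor(W / (s * scale))`` columns per magnification.
    """
    if tile_size < 1:
        raise ValueError("tile_size must be >= 1")
    bad = set(magnifications) - set(MAGNIFICATIONS)
    if bad:
        raise MagnificationError(f"unsupported magnifications: {sorted(bad)}")
    w0, h0 = slide.level_dims[0]
    tiles: list[TileRef] = []
    for mag in [m for m in MAGNIFICATIONS if m in magnifications]:
        step = tile_size * _mag_downsample(slide, mag)
        for gy in range(h0 // step):
            for gx in range(w0 // step):
                tiles.append(TileRef(
                    slide_id=slide.slide_id,
                    magnification=mag,
                    grid_xy=(gx, gy),
                    origin_level0=(gx * step, gy * step),
                    size_px=tile_size,
                ))
    return tiles


def read_tile(slide: SlideRef, tile: TileRef) -> np.ndarray:
    """Read one tile's pixels as (size, size, 3) uint8.

    20x tiles come from the pyramid level whose downsample is nearest 2 (if
    within 1 %); otherwise from 2x area-averaged level-0 pixels.
    """
    x0, y0, x1, y1 = tile.window_level0
    w0, h0 = slide.level_dims[0]
    if x1 > w0 or y1 > h0:
        raise ValueError(f"tile window {tile.window_level0} exceeds level-0 dims")
    ds = tile.scale
    level = None
    for i, d in enumerate(slide.level_downsamples):
        if abs(d - ds) / ds < 0.01:
            level = i
            break
    if level is not None:
        arr = read_level(slide, level)
        s = tile.size_px
        gx, gy = x0 // ds, y0 // ds
        out = arr[gy:gy + s, gx:gx + s]
    else:
        arr = read_level(slide, 0)[y0:y1, x0:x1]
        out = arr.reshape(tile.size_px, ds, tile.size_px, ds, -1).mean(axis=(1, 3))
        out = np.round(out).astype(np.uint8)
    if out.ndim == 2:
        out = np.stack([out] * 3, axis=-1)
    return np.ascontiguousarray(out[..., :3])


@dataclass
class RoiSet:
    """Pathologist-marked regions for one slide, level-0 pixel coordinates."""

    slide_id: str
    polygons: list[Polygon]

    @property
    def union(self):
        return shapely.union_all(self.polygons)

    @property
    def area(self) -> float:
        return float(self.union.area)


def load_roi(annotation_file: str | Path, slide_id: str | None = None) -> RoiSet:
    """Load ROI polygons from a GeoJSON annotation file.

    Accepts FeatureCollection / Feature / bare geometry; MultiPolygons are
    split into their parts; non-polygonal features are skipped.  Raises
    :class:`EmptyRoiError` when no polygon survives.
    """
    annotation_file = Path(annotation_file)
    with open(annotation_file) as fh:
        data = json.load(fh)
    if data.get("type") == "FeatureCollection":
        geoms = [f.get("geometry") for f in data.get("features", [])]
    elif data.get("type") == "Feature":
        geoms = [data.get("geometry")]
    else:
        geoms = [data]
    polygons: list[Polygon] = []
    for geom in geoms:
        if geom is None:
            continue
        g = shapely_shape(geom)  # raises on malformed geometry
        if isinstance(g, Polygon):
            polygons.append(g)
        elif isinstance(g, MultiPolygon):
            polygons.extend(g.geoms)
    if not polygons:
        raise EmptyRoiError(f"no polygonal features in {annotation_file}")
    for p in polygons:
        if not p.is_valid:
            raise ValueError(f"invalid polygon geometry in {annotation_file}")
    return RoiSet(slide_id=slide_id or annotation_file.stem, polygons=polygons)


def tile_in_roi(tile: TileRef, rois: RoiSet) -> bool:
    """True iff the tile's center point lies inside any ROI polygon.

    Boundary points count as inside; points inside holes do not.
    """
    pt = Point(*tile.center_level0)
    return any(p.covers(pt) for p in rois.polygons)
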