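"""Synthetic slides and feature bags with known ground truth.

Every pipeline stage is testable without external data:

* :func:`make_toy_slide` renders a small pyramidal TIFF emulating an H&E
  scan — bright background, a dark tissue block carrying a class-specific
  spot texture inside a marked ROI, and saturated-red blood blobs — plus the
  ROI as GeoJSON and a ground-truth tile table.  Geometry is aligned to the
  512-px level-0 grid so each tile is unambiguously background, tissue, or
  blood-contaminated.
* :func:`make_feature_bags` draws pre-encoded bags directly: class-0 bags
  are isotropic unit Gaussians; in class-1 bags a planted fraction of
  vectors is shifted by a fixed effect size along one seeded unit direction.
  The planted-vector indicator is returned so attention recovery can be
  scored against ground truth.

These fixtures emulate the *statistical* structure the pipeline relies on
(two separable texture/feature classes, background, blood, an enclosing
ROI), not the visual appearance of real stained tissue.
"""
from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
from skimage.draw import disk as disk_coords

from .datatypes import FeatureBag, TileRef, MAG_40X, MAG_20X

__all__ = [
    "SynthSlideConfig",
    "SynthBagConfig",
    "make_toy_slide",
    "make_feature_bags",
]

# flat colors chosen so grayscale separates cleanly: background ~235,
# tissue ~119, texture spots ~56, blood passes the red-cutoff rule
BACKGROUND_RGB = (235, 235, 235)
TISSUE_RGB = (130, 105, 160)
SPOT_RGB = (60, 40, 80)
BLOOD_RGB = (200, 30, 30)


@dataclass
class SynthSlideConfig:
    """Geometry and texture of one toy slide.

    All rectangles are (x, y) origin + edge length in level-0 pixels and
    must be multiples of 512 so that 40x and 20x tile grids both align.
    ``spot_density`` maps class name -> expected spots per pixel^2 of the
    textured region — the parameterized statistic distinguishing the
    classes.  ``blood_blobs`` blood disks (radius ``blood_radius``) are
    centered in untextured tissue tiles; radius 79 makes the disk cover
    ~30 % of its 256-px tile, sinking it below the 75 % tissue rule.
    """

    size: int = 2048
    tissue_origin: tuple[int, int] = (512, 512)
    tissue_size: int = 1024
    texture_origin: tuple[int, int] = (1024, 1024)
    texture_size: int = 512
    tumor_class: str = "A"
    spot_density: dict = field(default_factory=lambda: {"A": 1e-4, "B": 6e-4})
    spot_radius: int = 5
    blood_blobs: int = 2
    blood_radius: int = 79
    n_levels: int = 3
    seed: int = 0

    def __post_init__(self) -> None:
        for ox, oy, s, name in [(*self.tissue_origin, self.tissue_size, "tissue"),
                                (*self.texture_origin, self.texture_size, "texture")]:
            if ox < 0 or oy < 0 or ox + s > self.size or oy + s > self.size:
                raise ValueError(f"{name} region exceeds image bounds")
        tx, ty = self.texture_origin
        ox, oy = self.tissue_origin
        if not (ox <= tx and oy <= ty and
                tx + self.texture_size <= ox + self.tissue_size and
                ty + self.texture_size <= oy + self.tissue_size):
            raise ValueError("texture region must lie inside the tissue region")
        if self.tumor_class not in self.spot_density:
            raise ValueError(f"no spot density for class {self.tumor_class!r}")


def _downsample2(arr: np.ndarray) -> np.ndarray:
    h, w = arr.shape[:2]
    out = arr.reshape(h // 2, 2, w // 2, 2, -1).mean(axis=(1, 3))
    return np.round(out).astype(np.uint8)


def _tile_truth(tissue: np.ndarray, blood: np.ndarray, texture: np.ndarray,
                size: int) -> pd.DataFrame:
    rows = []
    for mag, step in ((MAG_40X, 256), (MAG_20X, 512)):
        for gy in range(tissue.shape[0] // step):
            for gx in range(tissue.shape[1] // step):
                sl = np.s_[gy * step:(gy + 1) * step, gx * step:(gx + 1) * step]
                blood_frac = float(blood[sl].mean())
                tissue_frac = float((tissue[sl] & ~blood[sl]).mean())
                keep = tissue_frac > 0.75
                if tissue[sl].mean() < 0.5:
                    category = "background"
                elif blood_frac > 0 and not keep:
                    category = "blood"
                elif texture[sl].mean() > 0.5:
                    category = "tissue_texture"
                else:
                    category = "tissue"
                rows.append(dict(mag=mag, grid_x=gx, grid_y=gy,
                                 origin_x=gx * step, origin_y=gy * step,
                                 category=category, tissue_frac=tissue_frac,
                                 blood_frac=blood_frac, keep=keep))
    return pd.DataFrame(rows)


def make_toy_slide(config: SynthSlideConfig, out_dir: str | Path,
                   slide_id: str = "toy") -> tuple[Path, Path, pd.DataFrame]:
    """Render one toy slide; write pyramid TIFF, ROI GeoJSON and truth CSV.

    Returns (tiff_path, roi_path, ground_truth_table).  Byte-identical
    output for identical configs.
    """
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    n = cfg.size
    img = np.empty((n, n, 3), dtype=np.uint8)
    img[:] = BACKGROUND_RGB
    tissue = np.zeros((n, n), dtype=bool)
    blood = np.zeros((n, n), dtype=bool)
    texture = np.zeros((n, n), dtype=bool)

    ox, oy = cfg.tissue_origin
    ts = cfg.tissue_size
    tissue[oy:oy + ts, ox:ox + ts] = True
    img[tissue] = TISSUE_RGB

    # class texture: Poisson number of dark spots inside the texture region
    tx, ty, s = *cfg.texture_origin, cfg.texture_size
    texture[ty:ty + s, tx:tx + s] = True
    density = cfg.spot_density[cfg.tumor_class]
    n_spots = rng.poisson(density * s * s)
    r = cfg.spot_radius
    for _ in range(n_spots):
        cx = rng.integers(tx + r, tx + s - r)
        cy = rng.integers(ty + r, ty + s - r)
        rr, cc = disk_coords((cy, cx), r, shape=(n, n))
        img[rr, cc] = SPOT_RGB

    # blood blobs centered in untextured 40x tissue tiles
    candidates = []
    for gy in range(n // 256):
        for gx in range(n // 256):
            sl = np.s_[gy * 256:(gy + 1) * 256, gx * 256:(gx + 1) * 256]
            if tissue[sl].all() and not texture[sl].any():
                candidates.append((gx, gy))
    chosen = rng.choice(len(candidates), size=min(cfg.blood_blobs, len(candidates)),
                        replace=False)
    for k in chosen:
        gx, gy = candidates[k]
        cy, cx = gy * 256 + 128, gx * 256 + 128
        rr, cc = disk_coords((cy, cx), cfg.blood_radius, shape=(n, n))
        img[rr, cc] = BLOOD_RGB
        blood[rr, cc] = True

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    tiff_path = out_dir / f"{slide_id}.tiff"
    with tifffile.TiffWriter(tiff_path) as tw:
        level = img
        for _ in range(cfg.n_levels):
            tw.write(level, tile=(256, 256), photometric="rgb")
            if min(level.shape[:2]) // 2 >= 256:
                level = _downsample2(level)
            else:
                break

    rx0, ry0 = cfg.texture_origin
    rx1, ry1 = rx0 + cfg.texture_size, ry0 + cfg.texture_size
    roi_path = out_dir / f"{slide_id}_roi.geojson"
    roi = {"type": "FeatureCollection", "features": [{
        "type": "Feature",
        "geometry": {"type": "Polygon", "coordinates": [
            [[rx0, ry0], [rx1, ry0], [rx1, ry1], [rx0, ry1], [rx0, ry0]]]},
        "properties": {"classification": "Tumor"},
    }]}
    with open(roi_path, "w") as fh:
        json.dump(roi, fh)

    truth = _tile_truth(tissue, blood, texture, n)
    truth.insert(0, "slide_id", slide_id)
    truth.to_csv(out_dir / f"{slide_id}_truth.csv", index=False)
    return tiff_path, roi_path, truth


@dataclass
class SynthBagConfig:
    """Pre-encoded bag cohort with a planted discriminative signal.

    Class-1 bags carry a fraction ``planted_frac`` of vectors mean-shifted
    by ``effect_size`` along a fixed seeded unit direction; all other
    vectors (and every class-0 vector) are N(0, I_dim).  ``frac_20x`` of
    each bag's synthetic tile refs are labelled 20x (features identical in
    law) so magnification-dependent statistics can be exercised.
    """

    patients_per_class: int = 40
    bag_size: int = 200
    dim: int = 128
    planted_frac: float = 0.1
    effect_size: float = 1.5
    frac_20x: float = 0.25
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.planted_frac <= 1:
            raise ValueError("planted_frac must be in (0, 1]")
        if self.effect_size < 0:
            raise ValueError("effect_size must be >= 0")


def _synthetic_tiles(pid: str, n: int, n20: int) -> list[TileRef]:
    tiles = []
    for k in range(n):
        mag = MAG_20X if k < n20 else MAG_40X
        step = 512 if mag == MAG_20X else 256
        idx = k if k < n20 else k - n20
        tiles.append(TileRef(slide_id=pid, magnification=mag,
                             grid_xy=(idx % 32, idx // 32),
                             origin_level0=((idx % 32) * step, (idx // 32) * step)))
    return tiles


def make_feature_bags(config: SynthBagConfig
                      ) -> tuple[list[FeatureBag], list[np.ndarray], np.ndarray]:
    """Generate the two-class bag cohort.

    Returns (bags, planted, direction): one boolean planted-vector indicator
    per bag, and the unit direction u used for the mean shift.  Bag labels
    are 0/1; deterministic given ``config.seed``.
    """
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    u = rng.standard_normal(cfg.dim)
    u /= np.linalg.norm(u)
    n_planted = max(1, int(round(cfg.planted_frac * cfg.bag_size)))
    n20 = int(round(cfg.frac_20x * cfg.bag_size))
    bags, planted = [], []
    for label in (0, 1):
        for p in range(cfg.patients_per_class):
            pid = f"c{label}_p{p:03d}"
            X = rng.standard_normal((cfg.bag_size, cfg.dim))
            flag = np.zeros(cfg.bag_size, dtype=bool)
            if label == 1:
                idx = rng.choice(cfg.bag_size, size=n_planted, replace=False)
                X[idx] += cfg.effect_size * u
                flag[idx] = True
            bags.append(FeatureBag(patient_id=pid, features=X,
                                   tiles=_synthetic_tiles(pid, cfg.bag_size, n20),
                                   label=label))
            planted.append(flag)
    return bags, planted, u
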