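"""End-to-end slide processing: tiling, QC, encoding, bag assembly."""
from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .datatypes import MAGNIFICATIONS, FeatureBag, SlideRef, TileQC
from .features import Encoder, FeatureStore, assemble_bag
from .qc import QCParams, build_tissue_mask, tile_keep_decision
from .slides import RoiSet, build_tile_grid, open_slide, read_level, read_tile

__all__ = ["qc_slide", "process_slide", "qc_table"]


def qc_slide(slide: SlideRef, roi: RoiSet | None = None,
             tile_size: int = 256, magnifications=MAGNIFICATIONS,
             params: QCParams = QCParams()) -> list[TileQC]:
    """Run tissue masking and per-tile QC over a slide's full tile grid.

    The Otsu threshold is computed once on the lowest-resolution level and
    re-applied to every tile; tiles whose center falls outside the ROI (when
    given) are treated as background and dropped.
    """
    thumb = read_level(slide, len(slide.level_dims) - 1)
    mask = build_tissue_mask(thumb, slide_id=slide.slide_id,
                             level=len(slide.level_dims) - 1, params=params)
    tiles = build_tile_grid(slide, tile_size, magnifications)
    results = []
    for t in tiles:
        if roi is not None:
            from .slides import tile_in_roi
            if not tile_in_roi(t, roi):
                results.append(TileQC(tile=t, tissue_frac=0.0, blood_frac=0.0,
                                      keep=False))
                continue
        rgb = read_tile(slide, t)
        results.append(tile_keep_decision(rgb, mask.otsu_threshold, tile=t,
                                          params=params))
    return results


def qc_table(qc: list[TileQC]) -> pd.DataFrame:
    """TileQC records as a flat table."""
    return pd.DataFrame([
        dict(slide_id=q.tile.slide_id, mag=q.tile.magnification,
             grid_x=q.tile.grid_xy[0], grid_y=q.tile.grid_xy[1],
             tissue_frac=q.tissue_frac, blood_frac=q.blood_frac, keep=q.keep)
        for q in qc])


def process_slide(slide_path: str | Path, encoder: Encoder,
                  store: FeatureStore, patient_id: str | None = None,
                  roi: RoiSet | None = None, label: int | None = None,
                  params: QCParams = QCParams()) -> FeatureBag:
    """Slide file -> QC -> cached encoding -> one patient feature bag."""
    slide = open_slide(slide_path)
    pid = patient_id or slide.slide_id
    if slide.slide_id in store:
        tiles, feats = store.get(slide.slide_id, encoder.encoder_id)
        bag_feats = {t: f for t, f in zip(tiles, feats)}
        qc = [TileQC(tile=t, tissue_frac=1.0, blood_frac=0.0, keep=True)
              for t in tiles]
        return assemble_bag(pid, qc, bag_feats, label=label)
    qc = qc_slide(slide, roi=roi, params=params)
    kept = [q for q in qc if q.keep]
    if not kept:
        from .datatypes import EmptyBagError
        raise EmptyBagError(f"no tiles passed QC on {slide_path}")
    images = np.stack([read_tile(slide, q.tile) for q in kept])
    feats = encoder.encode(images)
    store.put(slide.slide_id, [q.tile for q in kept], feats, encoder.encoder_id)
    by_tile = {q.tile: f for q, f in zip(kept, feats)}
    return assemble_bag(pid, kept, by_tile, label=label)
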