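"""Attention-map statistics, ROI enrichment and QuPath export.

For interpretation, a trained model's per-tile attention values (taken from
the predicted class's branch) are rank-normalized to [0, 1] and grouped into
five rank-quintile bins rendered on a red-to-blue gradient: bin 1 (blue,
0-20 %, least important) up to bin 5 (red, 80-100 %, most important).
Enrichment of high-attention tiles inside a pathologist-marked ROI, the
share of 20x tiles among high-attention tiles, and the stability of the
ranking across Monte Carlo runs quantify where the network looks.
"""
from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
from scipy.stats import rankdata, spearmanr

from .datatypes import MAG_20X, MAG_40X, TileRef, UndefinedMetricError
from .slides import RoiSet, tile_in_roi

__all__ = [
    "AttentionMap",
    "RoiAttentionStats",
    "rank_and_bin",
    "roi_proportions",
    "aggregate_proportions",
    "magnification_share",
    "cross_run_stability",
    "export_qupath",
    "BIN_COLORS",
]

#: rank-quintile colors, bin 1 (least important) .. bin 5 (most important)
BIN_COLORS = {
    1: (0, 0, 255),      # blue
    2: (135, 206, 250),  # light blue
    3: (128, 128, 128),  # gray
    4: (255, 165, 0),    # orange
    5: (255, 0, 0),      # red
}

HIGH_BINS = frozenset({4, 5})


@dataclass
class AttentionMap:
    """One patient's ranked attention map for one run."""

    patient_id: str
    run: int
    predicted_class: int
    tiles: list[TileRef]
    attention: np.ndarray  # raw weights of the predicted class, length n
    rank: np.ndarray       # normalized rank in [0, 1], average ties
    bin: np.ndarray        # quintile bin 1..5


@dataclass
class RoiAttentionStats:
    """Bin-proportion vectors inside/outside the ROI (None when the region
    holds no tiles)."""

    patient_id: str
    run: int
    inside: Optional[np.ndarray]
    outside: Optional[np.ndarray]
    n_inside: int
    n_outside: int


def _normalized_ranks(values: np.ndarray) -> np.ndarray:
    n = len(values)
    if n == 1:
        return np.array([0.5])
    return (rankdata(values, method="average") - 1.0) / (n - 1.0)


def _bins_from_ranks(ranks: np.ndarray) -> np.ndarray:
    return np.clip(np.ceil(ranks * 5).astype(int), 1, 5)


def rank_and_bin(tiles: Sequence[TileRef], attention: np.ndarray,
                 patient_id: str = "", run: int = 0, predicted_class: int = 0,
                 scope: str = "joint") -> AttentionMap:
    """Rank attention values and assign quintile bins.

    ``scope='joint'`` ranks across both magnifications together (the
    default); ``scope='per_magnification'`` recomputes ranks within each
    magnification's own map.  Ties receive average ranks; bins are
    ceil(rank * 5) clamped to [1, 5].
    """
    attention = np.asarray(attention, dtype=float)
    if len(attention) == 0:
        raise ValueError("attention map needs at least one tile")
    if len(tiles) != len(attention):
        raise ValueError("tiles/attention length mismatch")
    if scope == "joint":
        ranks = _normalized_ranks(attention)
    elif scope == "per_magnification":
        ranks = np.empty(len(attention))
        mags = np.array([t.magnification for t in tiles])
        for mag in np.unique(mags):
            sel = mags == mag
            ranks[sel] = _normalized_ranks(attention[sel])
    else:
        raise ValueError(f"unknown scope {scope!r}")
    return AttentionMap(patient_id=patient_id, run=run,
                        predicted_class=predicted_class, tiles=list(tiles),
                        attention=attention, rank=ranks,
                        bin=_bins_from_ranks(ranks))


def _bin_histogram(bins: np.ndarray) -> np.ndarray:
    h = np.bincount(bins, minlength=6)[1:6].astype(float)
    h /= h.sum()
    assert abs(h.sum() - 1.0) < 1e-9
    return h


def roi_proportions(amap: AttentionMap, rois: RoiSet,
                    magnification: str | None = MAG_20X) -> RoiAttentionStats:
    """Bin-proportion vectors of tiles inside vs outside the ROI.

    By default only the 20x entries of the map are considered.  Each region's
    vector is its tiles' bin histogram normalized by the region's tile count;
    an empty region yields None and is excluded from aggregation.
    """
    sel = np.arange(len(amap.tiles))
    if magnification is not None:
        sel = np.array([i for i in sel
                        if amap.tiles[i].magnification == magnification], dtype=int)
    inside_mask = np.array([tile_in_roi(amap.tiles[i], rois) for i in sel],
                           dtype=bool)
    bins = amap.bin[sel]
    inside_bins = bins[inside_mask]
    outside_bins = bins[~inside_mask]
    return RoiAttentionStats(
        patient_id=amap.patient_id, run=amap.run,
        inside=_bin_histogram(inside_bins) if len(inside_bins) else None,
        outside=_bin_histogram(outside_bins) if len(outside_bins) else None,
        n_inside=int(inside_mask.sum()),
        n_outside=int((~inside_mask).sum()),
    )


def aggregate_proportions(stats: Sequence[RoiAttentionStats]
                          ) -> tuple[Optional[np.ndarray], Optional[np.ndarray]]:
    """Unweighted mean of defined per-map proportion vectors, per region."""
    ins = [s.inside for s in stats if s.inside is not None]
    outs = [s.outside for s in stats if s.outside is not None]
    return (np.mean(ins, axis=0) if ins else None,
            np.mean(outs, axis=0) if outs else None)


def magnification_share(amap: AttentionMap,
                        high_bins: frozenset = HIGH_BINS) -> dict:
    """How much of the high-attention mass sits at 20x.

    ``share`` = (# 20x tiles in the high bins) / (# tiles in the high bins);
    ``rate_20x``/``rate_40x`` normalize each magnification's high-bin count
    by its own tile total.  Requires joint-scope ranks.
    """
    mags = np.array([t.magnification for t in amap.tiles])
    high = np.isin(amap.bin, list(high_bins))
    n_high = int(high.sum())
    if n_high == 0:
        raise UndefinedMetricError("no tiles in the high-attention bins")
    n20_high = int((high & (mags == MAG_20X)).sum())
    out = {"share_20x": n20_high / n_high, "n_high": n_high}
    for mag, key in ((MAG_20X, "rate_20x"), (MAG_40X, "rate_40x")):
        total = int((mags == mag).sum())
        out[key] = float((high & (mags == mag)).sum() / total) if total else np.nan
    return out


def cross_run_stability(maps: Sequence[AttentionMap]) -> dict:
    """Spearman rank correlation of attention between every pair of runs.

    All maps must cover the identical tile set (matched by TileRef).
    Returns the per-pair correlations and their mean.
    """
    if len(maps) < 2:
        raise ValueError("need at least 2 runs")
    ref = maps[0]
    ref_index = {t: i for i, t in enumerate(ref.tiles)}
    aligned = []
    for m in maps:
        if set(m.tiles) != set(ref_index):
            raise ValueError(f"tile sets differ between runs "
                             f"({m.patient_id}, run {m.run})")
        order = np.array([ref_index[t] for t in m.tiles])
        vals = np.empty(len(order))
        vals[order] = m.attention
        aligned.append(vals)
    corrs = []
    for i in range(len(aligned)):
        for j in range(i + 1, len(aligned)):
            rho = spearmanr(aligned[i], aligned[j]).statistic
            corrs.append(float(rho))
    corrs = np.asarray(corrs)
    return {"pairwise": corrs, "mean": float(corrs.mean())}


def export_qupath(amap: AttentionMap, path: str | Path | None = None) -> dict:
    """QuPath-importable GeoJSON: one closed square polygon per tile.

    Coordinates are level-0 pixels; properties carry the raw attention,
    normalized rank, bin, magnification and the bin's RGB gradient color.
    """
    features = []
    for tile, att, rank, b in zip(amap.tiles, amap.attention, amap.rank, amap.bin):
        x0, y0, x1, y1 = tile.window_level0
        ring = [[x0, y0], [x1, y0], [x1, y1], [x0, y1], [x0, y0]]
        features.append({
            "type": "Feature",
            "geometry": {"type": "Polygon", "coordinates": [ring]},
            "properties": {
                "patient_id": amap.patient_id,
                "run": amap.run,
                "magnification": tile.magnification,
                "grid_x": tile.grid_xy[0],
                "grid_y": tile.grid_xy[1],
                "attention": float(att),
                "rank": float(rank),
                "bin": int(b),
                "color": list(BIN_COLORS[int(b)]),
                "objectType": "annotation",
            },
        })
    collection = {"type": "FeatureCollection", "features": features}
    if path is not None:
        with open(path, "w") as fh:
            json.dump(collection, fh)
    return collection
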