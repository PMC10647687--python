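"""Attention ranking, quintile bins, ROI enrichment, stability, export."""
import json

import numpy as np
import pytest

from wsimil import (
    TileRef,
    aggregate_proportions,
    cross_run_stability,
    export_qupath,
    load_roi,
    magnification_share,
    rank_and_bin,
    roi_proportions,
)
from wsimil.attention_maps import BIN_COLORS
from wsimil.datatypes import UndefinedMetricError
from wsimil.slides import RoiSet
from shapely.geometry import Polygon


def _tiles(n, mag="20x", slide="s"):
    step = 512 if mag == "20x" else 256
    return [TileRef(slide_id=slide, magnification=mag, grid_xy=(i % 16, i // 16),
                    origin_level0=((i % 16) * step, (i // 16) * step))
            for i in range(n)]


class TestRankAndBin:
    def test_five_distinct_values(self):
        amap = rank_and_bin(_tiles(5), [0.1, 0.2, 0.3, 0.4, 0.5])
        assert np.allclose(sorted(amap.rank), [0, 0.25, 0.5, 0.75, 1.0])
        assert sorted(amap.bin) == [1, 2, 3, 4, 5]

    def test_all_ties_middle_bin(self):
        amap = rank_and_bin(_tiles(6), np.full(6, 0.3))
        assert np.allclose(amap.rank, 0.5)
        assert (amap.bin == 3).all()

    def test_top_tile_is_bin_5(self, rng):
        vals = rng.random(50)
        amap = rank_and_bin(_tiles(50), vals)
        assert amap.bin[np.argmax(vals)] == 5
        assert amap.bin[np.argmin(vals)] == 1

    def test_bins_conserve_counts(self, rng):
        n = 73
        amap = rank_and_bin(_tiles(n), rng.random(n))
        assert np.bincount(amap.bin, minlength=6)[1:].sum() == n

    def test_per_magnification_scope(self, rng):
        tiles = _tiles(10, "40x") + _tiles(10, "20x")
        vals = np.concatenate([rng.random(10), rng.random(10) + 100.0])
        joint = rank_and_bin(tiles, vals, scope="joint")
        permag = rank_and_bin(tiles, vals, scope="per_magnification")
        # jointly, every 20x tile outranks every 40x tile
        assert joint.rank[10:].min() > joint.rank[:10].max()
        # per magnification each map spans the full rank range
        assert permag.rank[:10].min() == 0.0 and permag.rank[:10].max() == 1.0
        assert permag.rank[10:].min() == 0.0 and permag.rank[10:].max() == 1.0


def _roi_rect(x0, y0, x1, y1):
    return RoiSet("s", [Polygon([(x0, y0), (x1, y0), (x1, y1), (x0, y1)])])


class TestRoiProportions:
    def test_top_quintile_inside_bottom_outside(self):
        tiles = _tiles(10, "20x")
        # first 5 tiles (x < 2560) get top values, inside ROI covering them
        vals = np.array([10, 9, 8, 7, 6, 1, 2, 3, 4, 5], dtype=float)
        amap = rank_and_bin(tiles, vals)
        rois = _roi_rect(0, 0, 2560, 512)
        stats = roi_proportions(amap, rois)
        assert stats.n_inside == 5 and stats.n_outside == 5
        assert stats.inside[4] > stats.outside[4]
        assert np.isclose(stats.inside.sum(), 1.0)
        assert np.isclose(stats.outside.sum(), 1.0)

    def test_pure_separation_one_hot(self):
        tiles = _tiles(10, "20x")
        vals = np.array([10, 9, 8, 7, 6, 5, 4, 3, 2, 1], dtype=float)
        amap = rank_and_bin(tiles, vals)
        # ranks 1.0..0.0 -> bins 5,5,4,4,3,3,2,2,1,1; ROI covers the two bin-5 tiles
        rois = _roi_rect(0, 0, 1024, 512)
        stats = roi_proportions(amap, rois)
        assert np.allclose(stats.inside, [0, 0, 0, 0, 1])
        assert stats.outside[4] == 0.0

    def test_uniform_mixture_flat_proportions(self, rng):
        n = 4000
        tiles = _tiles(n, "20x")
        amap = rank_and_bin(tiles, rng.random(n))
        rois = _roi_rect(0, 0, 16 * 512, 512 * (n // 32))  # half the rows
        stats = roi_proportions(amap, rois)
        for v in (stats.inside, stats.outside):
            assert np.allclose(v, 0.2, atol=0.03)

    def test_roi_covering_everything_outside_undefined(self):
        tiles = _tiles(4, "20x")
        amap = rank_and_bin(tiles, [1.0, 2.0, 3.0, 4.0])
        stats = roi_proportions(amap, _roi_rect(0, 0, 10 ** 6, 10 ** 6))
        assert stats.outside is None
        assert np.isclose(stats.inside.sum(), 1.0)

    def test_aggregate_skips_undefined(self):
        tiles = _tiles(4, "20x")
        amap = rank_and_bin(tiles, [1.0, 2.0, 3.0, 4.0])
        s_all = roi_proportions(amap, _roi_rect(0, 0, 10 ** 6, 10 ** 6))
        s_half = roi_proportions(amap, _roi_rect(0, 0, 1024, 512))
        inside, outside = aggregate_proportions([s_all, s_half])
        assert inside is not None and outside is not None
        assert np.isclose(outside.sum(), 1.0)


class TestMagnificationShare:
    def test_share_arithmetic(self):
        tiles = _tiles(30, "20x") + _tiles(10, "40x") + _tiles(60, "40x", slide="t")
        vals = np.concatenate([np.full(40, 10.0), np.zeros(60)])  # 40 high tiles
        amap = rank_and_bin(tiles, vals)
        out = magnification_share(amap)
        assert out["share_20x"] == pytest.approx(30 / 40)

    def test_all_high_at_40x_zero_share(self):
        tiles = _tiles(10, "40x") + _tiles(10, "20x")
        vals = np.concatenate([np.full(10, 5.0), np.zeros(10)])
        out = magnification_share(rank_and_bin(tiles, vals))
        assert out["share_20x"] == 0.0

    def test_no_high_bins_undefined(self):
        tiles = _tiles(4, "20x")
        amap = rank_and_bin(tiles, [1.0, 2.0, 3.0, 4.0])
        amap.bin = np.array([1, 1, 2, 2])  # force no high bins
        with pytest.raises(UndefinedMetricError):
            magnification_share(amap)


class TestCrossRunStability:
    def _map(self, vals, run=0):
        return rank_and_bin(_tiles(len(vals)), vals, run=run)

    def test_identical_maps_correlation_one(self, rng):
        vals = rng.random(30)
        out = cross_run_stability([self._map(vals, 0), self._map(vals.copy(), 1)])
        assert out["mean"] == pytest.approx(1.0)

    def test_reversed_ranks_minus_one(self):
        vals = np.arange(20, dtype=float)
        out = cross_run_stability([self._map(vals), self._map(vals[::-1].copy())])
        assert out["mean"] == pytest.approx(-1.0)

    def test_independent_ranks_near_zero(self, rng):
        maps = [self._map(rng.permutation(400).astype(float), run=r)
                for r in range(5)]
        out = cross_run_stability(maps)
        assert abs(out["mean"]) < 0.1

    def test_mismatched_tiles_raise(self, rng):
        a = self._map(rng.random(5))
        b = rank_and_bin(_tiles(5, "40x"), rng.random(5))
        with pytest.raises(ValueError):
            cross_run_stability([a, b])

    def test_alignment_by_tileref_not_order(self, rng):
        vals = rng.random(12)
        a = self._map(vals)
        perm = rng.permutation(12)
        b = rank_and_bin([a.tiles[i] for i in perm], vals[perm], run=1)
        out = cross_run_stability([a, b])
        assert out["mean"] == pytest.approx(1.0)


class TestExportQupath:
    def test_square_rings_and_colors(self, tmp_path):
        tiles = _tiles(4, "40x")
        amap = rank_and_bin(tiles, [1.0, 2.0, 3.0, 4.0], patient_id="p")
        out = export_qupath(amap, tmp_path / "maps.geojson")
        assert len(out["features"]) == 4
        for f in out["features"]:
            ring = f["geometry"]["coordinates"][0]
            assert len(ring) == 5 and ring[0] == ring[-1]
        by_bin = {f["properties"]["bin"]: f["properties"]["color"]
                  for f in out["features"]}
        assert by_bin[5] == list(BIN_COLORS[5]) == [255, 0, 0]
        assert by_bin[1] == list(BIN_COLORS[1]) == [0, 0, 255]

    def test_round_trip_recovers_tile_squares(self, tmp_path):
        tiles = _tiles(6, "20x")
        amap = rank_and_bin(tiles, np.arange(6, dtype=float))
        path = tmp_path / "maps.geojson"
        export_qupath(amap, path)
        rois = load_roi(path)
        assert len(rois.polygons) == 6
        areas = sorted(p.area for p in rois.polygons)
        assert areas == [512 * 512.0] * 6
        bounds = {tuple(map(int, p.bounds)) for p in rois.polygons}
        expected = {t.window_level0 for t in tiles}
        assert bounds == expected
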