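"""Tile encoding and per-patient feature-bag assembly.

Tiles that pass QC are encoded once into fixed-length feature vectors and
cached on disk (HDF5, one group per slide).  The encoder is an interface:
any callable object exposing ``encode(images) -> (n, dim) float32`` with a
stable ``encoder_id`` plugs in.  The encoder shipped here is a seeded
pooled random projection — a synthetic-feature encoder that maps local
intensity statistics into a ``dim``-dimensional vector deterministically,
which is sufficient for texture-density signals and keeps every pipeline
stage runnable end to end.

A patient's bag concatenates the kept tiles of both magnifications in a
stable (magnification, grid_y, grid_x) order.
"""
from __future__ import annotations

from pathlib import Path
from typing import Protocol, Sequence, runtime_checkable

import h5py
import numpy as np

from .datatypes import (
    MAG_40X,
    MAG_20X,
    EmptyBagError,
    FeatureBag,
    FeatureVector,
    StaleCacheError,
    TileQC,
    TileRef,
)

__all__ = [
    "Encoder",
    "RandomProjectionEncoder",
    "encode_tiles",
    "FeatureStore",
    "assemble_bag",
    "discard_augment",
]

_MAG_CODE = {MAG_40X: 40, MAG_20X: 20}
_CODE_MAG = {v: k for k, v in _MAG_CODE.items()}


@runtime_checkable
class Encoder(Protocol):
    """Deterministic tile encoder contract."""

    encoder_id: str
    dim: int
    input_size: int

    def encode(self, images: np.ndarray) -> np.ndarray:
        """(n, s, s, 3) uint8 -> (n, dim) float32, deterministic."""
        ...


class RandomProjectionEncoder:
    """Seeded random-projection encoder over area-pooled tile intensities.

    Pixels are scaled to [0, 1], channel means subtracted, the tile is
    area-pooled to ``pool x pool`` per channel, flattened, and projected with
    a fixed N(0, 1/k) Gaussian matrix drawn once from ``seed``.  Deterministic
    given (seed, dim, pool); two byte-identical tiles map to identical
    vectors.
    """

    def __init__(self, dim: int = 1024, seed: int = 0, pool: int = 32,
                 input_size: int = 256,
                 channel_means: tuple[float, float, float] = (0.485, 0.456, 0.406)):
        if input_size % pool:
            raise ValueError("pool must divide input_size")
        self.dim = dim
        self.seed = seed
        self.pool = pool
        self.input_size = input_size
        self.channel_means = np.asarray(channel_means, dtype=np.float32)
        k = pool * pool * 3
        rng = np.random.default_rng(seed)
        self._proj = rng.standard_normal((k, dim)).astype(np.float32) / np.sqrt(k)
        self.encoder_id = f"randproj-d{dim}-s{seed}-p{pool}"

    def encode(self, images: np.ndarray) -> np.ndarray:
        images = np.asarray(images)
        if images.ndim == 3:
            images = images[None]
        n, h, w, c = images.shape
        if h != self.input_size or w != self.input_size or c != 3:
            raise ValueError(
                f"expected (n, {self.input_size}, {self.input_size}, 3) images, got {images.shape}")
        x = images.astype(np.float32) / 255.0 - self.channel_means
        r = self.input_size // self.pool
        pooled = x.reshape(n, self.pool, r, self.pool, r, 3).mean(axis=(2, 4))
        return pooled.reshape(n, -1) @ self._proj


def encode_tiles(images: Sequence[np.ndarray] | np.ndarray, encoder: Encoder,
                 tiles: Sequence[TileRef] | None = None):
    """Encode a batch of RGB tiles.

    Returns an (n, dim) float32 array, or a list of :class:`FeatureVector`
    when the matching ``tiles`` are supplied.
    """
    arr = np.asarray(images)
    feats = encoder.encode(arr)
    if tiles is None:
        return feats
    if len(tiles) != len(feats):
        raise ValueError("tiles and images length mismatch")
    return [FeatureVector(tile=t, values=v) for t, v in zip(tiles, feats)]


class FeatureStore:
    """HDF5 feature cache: one group per slide.

    Layout per slide group: ``features`` (n, d) float32 and ``tiles``
    (n, 5) int64 columns (mag, grid_x, grid_y, origin_x, origin_y); the
    group attribute ``encoder_id`` records provenance, and a read or append
    under a different encoder raises :class:`StaleCacheError` so features
    from distinct encoders can never silently mix.
    """

    def __init__(self, path: str | Path, mode: str = "a"):
        self.path = str(path)
        self._h5 = h5py.File(self.path, mode)

    def close(self) -> None:
        self._h5.close()

    def __enter__(self):
        return self

    def __exit__(self, *exc):
        self.close()

    def __contains__(self, slide_id: str) -> bool:
        return slide_id in self._h5

    def _check_encoder(self, grp, encoder_id: str) -> None:
        stored = grp.attrs.get("encoder_id")
        if stored is not None and encoder_id is not None and stored != encoder_id:
            raise StaleCacheError(
                f"cache for {grp.name} written by {stored!r}, requested {encoder_id!r}")

    def put(self, slide_id: str, tiles: Sequence[TileRef], features: np.ndarray,
            encoder_id: str, tile_size: int = 256) -> None:
        if slide_id in self._h5:
            self._check_encoder(self._h5[slide_id], encoder_id)
            del self._h5[slide_id]
        grp = self._h5.create_group(slide_id)
        table = np.array(
            [[_MAG_CODE[t.magnification], t.grid_xy[0], t.grid_xy[1],
              t.origin_level0[0], t.origin_level0[1]] for t in tiles], dtype=np.int64)
        grp.create_dataset("features", data=np.asarray(features, dtype=np.float32))
        grp.create_dataset("tiles", data=table.reshape(-1, 5))
        grp.attrs["encoder_id"] = encoder_id
        grp.attrs["tile_size"] = tile_size

    def get(self, slide_id: str, encoder_id: str | None = None
            ) -> tuple[list[TileRef], np.ndarray]:
        grp = self._h5[slide_id]
        if encoder_id is not None:
            self._check_encoder(grp, encoder_id)
        table = grp["tiles"][()]
        size = int(grp.attrs.get("tile_size", 256))
        tiles = [TileRef(slide_id=slide_id, magnification=_CODE_MAG[int(m)],
                         grid_xy=(int(gx), int(gy)), origin_level0=(int(ox), int(oy)),
                         size_px=size)
                 for m, gx, gy, ox, oy in table]
        return tiles, grp["features"][()]


def encode_slide(slide, kept_tiles: Sequence[TileRef], encoder: Encoder,
                 store: FeatureStore, read_tile_fn=None) -> np.ndarray:
    """Encode a slide's kept tiles through the cache.

    A cache hit returns the stored features bitwise without re-encoding.
    """
    from .slides import read_tile as _read_tile
    if slide.slide_id in store:
        tiles, feats = store.get(slide.slide_id, encoder.encoder_id)
        return feats
    reader = read_tile_fn or _read_tile
    images = np.stack([reader(slide, t) for t in kept_tiles])
    feats = encoder.encode(images)
    store.put(slide.slide_id, kept_tiles, feats, encoder.encoder_id)
    return feats


def _bag_order(tile: TileRef) -> tuple:
    # 40x block first, then 20x; row-major within a magnification
    return (0 if tile.magnification == MAG_40X else 1,
            tile.grid_xy[1], tile.grid_xy[0])


def assemble_bag(patient_id: str, qc: Sequence[TileQC],
                 features_by_tile: dict[TileRef, np.ndarray],
                 label: int | None = None) -> FeatureBag:
    """Build a patient's dual-magnification bag from kept tiles.

    Keeps exactly the tiles with ``keep=True``, ordered by
    (magnification, grid_y, grid_x); raises :class:`EmptyBagError` when no
    tile survives QC.
    """
    kept = sorted((q.tile for q in qc if q.keep), key=_bag_order)
    if not kept:
        raise EmptyBagError(f"no tiles passed QC for patient {patient_id!r}")
    feats = np.stack([features_by_tile[t] for t in kept])
    return FeatureBag(patient_id=patient_id, features=feats, tiles=kept, label=label)


def discard_augment(bag: FeatureBag, max_frac: float = 0.25,
                    rng: np.random.Generator | int | None = None) -> FeatureBag:
    """Randomly discard up to ``max_frac`` of a bag's vectors (training-time
    bag augmentation; off by default in the training protocol).

    The discarded fraction f is drawn ~ Uniform(0, max_frac), then
    floor(f*n) vectors are removed uniformly without replacement, preserving
    order, so at least ceil((1-max_frac)*n) vectors remain.
    """
    if not 0 <= max_frac < 1:
        raise ValueError("max_frac must be in [0, 1)")
    if max_frac == 0:
        return bag
    rng = np.random.default_rng(rng)
    n = len(bag)
    n_drop = int(np.floor(rng.uniform(0, max_frac) * n))
    if n_drop == 0:
        return bag
    drop = rng.choice(n, size=n_drop, replace=False)
    keep = np.setdiff1d(np.arange(n), drop)
    return FeatureBag(patient_id=bag.patient_id, features=bag.features[keep],
                      tiles=[bag.tiles[i] for i in keep], label=bag.label)
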