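"""Core domain types shared across the pipeline.

The unit of prediction is the *patient bag*: the ordered collection of
tile-level feature vectors (both magnifications) from one patient's
whole-slide image, labelled only at the bag level.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

#: tile edge length in pixels, at the tile's own magnification
DEFAULT_TILE_SIZE = 256

#: magnification identifiers; level 0 of the pyramid is assumed 40x-equivalent
MAG_40X = "40x"
MAG_20X = "20x"
MAGNIFICATIONS = (MAG_40X, MAG_20X)

#: level-0 pixels covered per tile pixel at each magnification
MAG_SCALE = {MAG_40X: 1, MAG_20X: 2}


class SlideReadError(IOError):
    """Slide file missing or not a readable pyramidal TIFF."""


class MagnificationError(ValueError):
    """Requested magnification cannot be derived from the pyramid."""


class EmptyRoiError(ValueError):
    """Annotation file contains no polygonal features."""


class DegenerateHistogramError(ValueError):
    """All pixels share one grey value; Otsu threshold undefined."""


class EmptyBagError(ValueError):
    """A patient has no tiles passing quality control."""


class StaleCacheError(RuntimeError):
    """Feature cache was written by a different encoder."""


class StratificationError(ValueError):
    """A class is too small to populate train/validation/test parts."""


class UndefinedMetricError(ValueError):
    """Metric requested on data where it is undefined (e.g. one class only)."""


@dataclass(frozen=True)
class SlideRef:
    """Handle to one pyramidal slide.

    ``level_dims`` lists (width, height) per pyramid level, level 0 first and
    strictly decreasing.  ``mpp_level0`` is micrometres per pixel at level 0
    (0.23 for a typical 40x scan).  Level 0 is taken to be
    ``base_magnification``-equivalent.
    """

    slide_id: str
    path: str
    level_dims: tuple[tuple[int, int], ...]
    mpp_level0: float = 0.23
    base_magnification: int = 40

    def __post_init__(self) -> None:
        if self.mpp_level0 <= 0:
            raise ValueError("mpp_level0 must be positive")
        for (w0, h0), (w1, h1) in zip(self.level_dims, self.level_dims[1:]):
            if not (w1 < w0 and h1 < h0):
                raise ValueError("level_dims must strictly decrease with level")

    @property
    def level_downsamples(self) -> tuple[float, ...]:
        w0, h0 = self.level_dims[0]
        return tuple((w0 / w + h0 / h) / 2 for w, h in self.level_dims)


@dataclass(frozen=True, order=True)
class TileRef:
    """One tile's position: grid coordinates plus its level-0 pixel window.

    The window is half-open, ``[x, x + s*scale) x [y, y + s*scale)`` in the
    level-0 frame, where ``scale`` is 1 at 40x and 2 at 20x.
    """

    slide_id: str
    magnification: str
    grid_xy: tuple[int, int]
    origin_level0: tuple[int, int]
    size_px: int = DEFAULT_TILE_SIZE

    def __post_init__(self) -> None:
        if self.magnification not in MAG_SCALE:
            raise MagnificationError(f"unknown magnification {self.magnification!r}")
        if min(self.origin_level0) < 0:
            raise ValueError("origin_level0 coordinates must be >= 0")

    @property
    def scale(self) -> int:
        return MAG_SCALE[self.magnification]

    @property
    def window_level0(self) -> tuple[int, int, int, int]:
        """(x0, y0, x1, y1) half-open window in level-0 pixels."""
        x, y = self.origin_level0
        s = self.size_px * self.scale
        return (x, y, x + s, y + s)

    @property
    def center_level0(self) -> tuple[float, float]:
        x0, y0, x1, y1 = self.window_level0
        return ((x0 + x1) / 2.0, (y0 + y1) / 2.0)


@dataclass
class TissueMask:
    """Binary tissue mask at one pyramid level (True = tissue)."""

    slide_id: str
    level: int
    mask: np.ndarray
    otsu_threshold: int

    def __post_init__(self) -> None:
        if not (0 <= self.otsu_threshold <= 255):
            raise ValueError("otsu threshold outside [0, 255]")


@dataclass(frozen=True)
class TileQC:
    """Per-tile quality-control verdict under the >75 % tissue rule."""

    tile: TileRef
    tissue_frac: float
    blood_frac: float
    keep: bool


@dataclass(frozen=True)
class FeatureVector:
    """A tile together with its encoded feature vector."""

    tile: TileRef
    values: np.ndarray


@dataclass
class FeatureBag:
    """A patient's ordered tile features across both magnifications.

    ``features`` is (n_tiles, d); ``tiles`` holds the matching TileRefs in the
    same order.  ``label`` is the class index when known.
    """

    patient_id: str
    features: np.ndarray
    tiles: list[TileRef]
    label: Optional[int] = None

    def __post_init__(self) -> None:
        self.features = np.asarray(self.features)
        if self.features.ndim != 2 or len(self.features) == 0:
            raise EmptyBagError(f"bag for {self.patient_id!r} is empty")
        if len(self.tiles) != len(self.features):
            raise ValueError("tiles and features length mismatch")
        if len(set(self.tiles)) != len(self.tiles):
            raise ValueError("duplicate tile refs in bag")
        if not np.all(np.isfinite(self.features)):
            raise ValueError("non-finite feature values")

    def __len__(self) -> int:
        return len(self.features)

    @property
    def dim(self) -> int:
        return self.features.shape[1]


@dataclass
class AttentionOutput:
    """Forward-pass result for one bag.

    ``attention`` is (C, n): per-class softmax weights over tiles, each row a
    distribution.  ``probabilities`` is the length-C softmax over class
    scores; ``scores`` the raw (pre-softmax) class scores.
    """

    attention: np.ndarray
    probabilities: np.ndarray
    scores: np.ndarray


@dataclass
class SplitPlan:
    """One Monte Carlo run's patient-level stratified partition.

    Each of ``train``/``val``/``test`` maps class label -> list of patient
    ids; parts are disjoint and their union is the cohort.
    """

    run: int
    seed: int
    train: dict
    val: dict
    test: dict

    def part_patients(self, part: str) -> list:
        groups = getattr(self, part)
        return [p for patients in groups.values() for p in patients]


@dataclass
class TrainConfig:
    """Training protocol for the attention network.

    One patient bag per optimization step; Adam with categorical
    cross-entropy; class-balanced epoch sampling limited by the minority
    class; early stopping on validation loss (patience epochs without
    improvement) suppressed before ``min_epochs``.
    """

    learning_rate: float = 1e-4
    weight_decay: float = 1e-5
    max_epochs: int = 400
    min_epochs: int = 100
    patience: int = 25
    hidden_trunk: int = 512
    hidden_gate: int = 256
    dropout: float = 0.25
    discard_augment_frac: float = 0.0  # up-to-25% bag discard; off by default
    seed: int = 0

    def __post_init__(self) -> None:
        if self.min_epochs > self.max_epochs:
            raise ValueError("min_epochs must be <= max_epochs")
        if self.patience < 1:
            raise ValueError("patience must be >= 1")


@dataclass
class TrainHistory:
    """Per-epoch losses plus the early-stopping outcome."""

    train_loss: list[float] = field(default_factory=list)
    val_loss: list[float] = field(default_factory=list)
    best_epoch: int = -1
    stop_reason: str = ""


@dataclass
class RunMetrics:
    """Evaluation-cohort metrics for one Monte Carlo run."""

    run: int
    tp: int
    fp: int
    tn: int
    fn: int
    sensitivity: float
    specificity: float
    balanced_accuracy: float
    roc_points: np.ndarray  # columns: threshold, sensitivity, specificity
    auc: float
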