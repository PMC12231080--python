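"""Planar raster grid primitives shared by every stage of the pipeline.

All rasters in this package live on a regular, north-up, planar metric grid:
pixel (0, 0) is the top-left cell, row indices increase southward, column
indices increase eastward, and cell centers sit half a pixel in from the
outer corner of the grid. There is no CRS machinery — coordinates are plain
meters in an arbitrary planar frame, which is all the synthetic study
conditions require.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import shapely
from shapely.geometry import box
from shapely.ops import unary_union


@dataclass(frozen=True)
class GridSpec:
    """Geometry of a raster grid.

    Parameters
    ----------
    n_rows, n_cols
        Grid dimensions; must be >= 1.
    pixel_size
        Cell edge length in meters (default 30, the Landsat-class grain the
        vegetation data emulate).
    origin_x, origin_y
        Planar coordinates of the *outer corner* of the top-left pixel.
        y decreases with increasing row index (north-up convention).
    """

    n_rows: int
    n_cols: int
    pixel_size: float = 30.0
    origin_x: float = 0.0
    origin_y: float = 0.0

    def __post_init__(self) -> None:
        if self.n_rows < 1 or self.n_cols < 1:
            raise ValueError("grid must have at least one row and column")
        if self.pixel_size <= 0:
            raise ValueError("pixel_size must be positive")

    @property
    def shape(self) -> tuple[int, int]:
        return (self.n_rows, self.n_cols)

    @property
    def n_cells(self) -> int:
        return self.n_rows * self.n_cols

    def x_centers(self) -> np.ndarray:
        return self.origin_x + (np.arange(self.n_cols) + 0.5) * self.pixel_size

    def y_centers(self) -> np.ndarray:
        return self.origin_y - (np.arange(self.n_rows) + 0.5) * self.pixel_size

    def center_of(self, rows: np.ndarray, cols: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Planar coordinates of the centers of the given cells."""
        rows = np.asarray(rows)
        cols = np.asarray(cols)
        x = self.origin_x + (cols + 0.5) * self.pixel_size
        y = self.origin_y - (rows + 0.5) * self.pixel_size
        return x, y

    def index_of(self, x: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Row/col indices of the cells containing the given points.

        Points outside the grid raise ``ValueError`` — callers that need
        clipping (e.g. nearest-cell lookup on coarse covariate grids that
        only nominally cover the fine grid) should use :meth:`clip_index`.
        """
        rows, cols = self._raw_index(x, y)
        if (rows < 0).any() or (rows >= self.n_rows).any() or (cols < 0).any() or (cols >= self.n_cols).any():
            raise ValueError("point(s) outside grid extent")
        return rows, cols

    def clip_index(self, x: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        rows, cols = self._raw_index(x, y)
        return (np.clip(rows, 0, self.n_rows - 1), np.clip(cols, 0, self.n_cols - 1))

    def _raw_index(self, x, y):
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        cols = np.floor((x - self.origin_x) / self.pixel_size).astype(int)
        rows = np.floor((self.origin_y - y) / self.pixel_size).astype(int)
        return rows, cols

    def center_meshgrid(self) -> tuple[np.ndarray, np.ndarray]:
        """(X, Y) arrays of cell-center coordinates, shape (n_rows, n_cols)."""
        return np.meshgrid(self.x_centers(), self.y_centers())


@dataclass
class Raster:
    """A single-band raster: a :class:`GridSpec` plus a value array."""

    spec: GridSpec
    values: np.ndarray
    nodata: float = -9999.0

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if self.values.shape != self.spec.shape:
            raise ValueError(
                f"value array shape {self.values.shape} != grid shape {self.spec.shape}"
            )

    def sample_nearest(self, x: np.ndarray, y: np.ndarray) -> np.ndarray:
        """Nearest-cell lookup at arbitrary planar points (clipped to grid).

        This is how coarse reanalysis-style grids are sampled at fine-pixel
        centers: each 30-m pixel reads the value of the coarse cell it falls
        in, with no interpolation.
        """
        rows, cols = self.spec.clip_index(x, y)
        return self.values[rows, cols]


def derive_rng(seed: int, *tags) -> np.random.Generator:
    """Independent, reproducible random stream for (seed, tags).

    Streams are keyed by the tag tuple so that e.g. adding fires to a run
    never perturbs the landscapes or detections of existing fires.
    """
    import zlib

    key = zlib.crc32(repr(tags).encode()) & 0x7FFFFFFF
    return np.random.default_rng(np.random.SeedSequence([int(seed) & 0x7FFFFFFF, key]))


def footprint_polygon(mask: np.ndarray, spec: GridSpec) -> shapely.Geometry:
    """Polygonal outline of a boolean cell mask (union of full cell squares).

    The returned (Multi)Polygon contains exactly the centers of the masked
    cells, so rasterizing it back by cell-center containment round-trips the
    mask. Holes are handled by the union.
    """
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != spec.shape:
        raise ValueError("mask shape does not match grid")
    if not mask.any():
        raise ValueError("empty mask has no footprint")
    px = spec.pixel_size
    boxes = []
    # one box per horizontal run of masked cells per row
    for i in range(spec.n_rows):
        row = mask[i]
        if not row.any():
            continue
        padded = np.concatenate(([False], row, [False]))
        d = np.diff(padded.astype(np.int8))
        starts = np.flatnonzero(d == 1)
        ends = np.flatnonzero(d == -1)
        y_top = spec.origin_y - i * px
        y_bot = y_top - px
        for s, e in zip(starts, ends):
            x0 = spec.origin_x + s * px
            x1 = spec.origin_x + e * px
            boxes.append(box(x0, y_bot, x1, y_top))
    return unary_union(boxes)


def rasterize_polygon(geom: shapely.Geometry, spec: GridSpec) -> np.ndarray:
    """Boolean mask of cells whose *centers* fall inside the polygon.

    Cell-center containment is the single rasterization convention used
    throughout (perimeters, prior burns, interior/buffer masks).
    """
    X, Y = spec.center_meshgrid()
    return shapely.contains_xy(geom, X.ravel(), Y.ravel()).reshape(spec.shape)
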