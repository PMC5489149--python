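"""Planar grid conventions, raster containers and I/O.

Every raster in a run lives on a shared planar metric grid (British National
Grid style): cells are half-open squares ``[x, x+res) x [y, y+res)`` named by
their lower-left corner, and a coarser grid whose resolution is an integer
multiple of a finer grid's — and which shares its origin — nests it exactly.
Rows are stored south-to-north: ``values[0, 0]`` is the cell whose lower-left
corner is the grid origin.

GeoTIFF interchange uses plain TIFF plus the ModelPixelScale / ModelTiepoint
tags, written and parsed directly with :mod:`tifffile`.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import tifffile

__all__ = [
    "GridSpec",
    "RasterLayer",
    "LandAreaRaster",
    "snap_to_cell",
    "land_area_map",
    "minmax_standardize",
    "read_geotiff",
    "write_geotiff",
    "GridError",
    "ExtentError",
    "AlignmentError",
    "DegenerateScaleError",
]

_TAG_MODEL_PIXEL_SCALE = 33550
_TAG_MODEL_TIEPOINT = 33922


class GridError(ValueError):
    """Base class for grid convention violations."""


class ExtentError(GridError):
    """A point falls outside the grid extent."""


class AlignmentError(GridError):
    """Two grids do not share an origin or do not nest."""


class DegenerateScaleError(ValueError):
    """Min-max standardization attempted on a constant field."""


@dataclass(frozen=True)
class GridSpec:
    """Geometry of a regular planar grid of square cells.

    Parameters
    ----------
    origin_easting, origin_northing
        Coordinates (metres) of the lower-left corner of the grid.
    resolution
        Cell side length in metres; must be positive.
    n_cols, n_rows
        Grid dimensions.
    crs_tag
        Opaque identifier for the coordinate reference system. Rasters are
        never reprojected; the tag only travels with the data.
    """

    origin_easting: float
    origin_northing: float
    resolution: float
    n_cols: int
    n_rows: int
    crs_tag: str = "EPSG:27700"

    def __post_init__(self) -> None:
        if self.resolution <= 0:
            raise GridError(f"resolution must be positive, got {self.resolution}")
        if self.n_cols < 1 or self.n_rows < 1:
            raise GridError("grid must contain at least one cell")

    @property
    def shape(self) -> tuple[int, int]:
        return (self.n_rows, self.n_cols)

    @property
    def extent(self) -> tuple[float, float, float, float]:
        """(min_easting, min_northing, max_easting, max_northing)."""
        return (
            self.origin_easting,
            self.origin_northing,
            self.origin_easting + self.n_cols * self.resolution,
            self.origin_northing + self.n_rows * self.resolution,
        )

    def cell_centroids(self) -> tuple[np.ndarray, np.ndarray]:
        """Easting/northing of every cell centre, each shaped (n_rows, n_cols)."""
        e = self.origin_easting + (np.arange(self.n_cols) + 0.5) * self.resolution
        n = self.origin_northing + (np.arange(self.n_rows) + 0.5) * self.resolution
        ee, nn = np.meshgrid(e, n)
        return ee, nn

    def nests(self, fine: "GridSpec") -> bool:
        """True if this (coarser) grid shares ``fine``'s origin and its
        resolution is an integer multiple of the fine resolution, with the
        extents compatible (coarse covers the same span)."""
        if (
            self.origin_easting != fine.origin_easting
            or self.origin_northing != fine.origin_northing
        ):
            return False
        ratio = self.resolution / fine.resolution
        if abs(ratio - round(ratio)) > 1e-9 or round(ratio) < 1:
            return False
        r = int(round(ratio))
        return fine.n_cols == self.n_cols * r and fine.n_rows == self.n_rows * r

    def coarsen(self, factor: int) -> "GridSpec":
        if self.n_cols % factor or self.n_rows % factor:
            raise AlignmentError("grid dimensions not divisible by factor")
        return replace(
            self,
            resolution=self.resolution * factor,
            n_cols=self.n_cols // factor,
            n_rows=self.n_rows // factor,
        )

    def refine(self, factor: int) -> "GridSpec":
        return replace(
            self,
            resolution=self.resolution / factor,
            n_cols=self.n_cols * factor,
            n_rows=self.n_rows * factor,
        )


@dataclass
class RasterLayer:
    """A single-band raster on a :class:`GridSpec`.

    ``kind`` is one of ``continuous``, ``categorical`` or ``binary``.
    ``nodata`` is the single sentinel value used for missing cells; use
    ``np.nan`` for continuous layers.
    """

    grid: GridSpec
    values: np.ndarray
    kind: str = "continuous"
    nodata: float = np.nan
    name: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if self.values.shape != self.grid.shape:
            raise GridError(
                f"values shape {self.values.shape} != grid shape {self.grid.shape}"
            )
        if self.kind not in ("continuous", "categorical", "binary"):
            raise GridError(f"unknown raster kind {self.kind!r}")

    def valid_mask(self) -> np.ndarray:
        if isinstance(self.nodata, float) and np.isnan(self.nodata):
            return ~np.isnan(self.values.astype(float))
        return self.values != self.nodata

    def copy(self) -> "RasterLayer":
        return RasterLayer(self.grid, self.values.copy(), self.kind, self.nodata, self.name)


@dataclass
class LandAreaRaster:
    """Per-cell land area in km², derived from a fine binary land mask."""

    grid: GridSpec
    area_km2: np.ndarray

    def __post_init__(self) -> None:
        self.area_km2 = np.asarray(self.area_km2, dtype=float)
        if self.area_km2.shape != self.grid.shape:
            raise GridError("area array does not match grid")
        cell_km2 = (self.grid.resolution / 1000.0) ** 2
        if np.any(self.area_km2 < -1e-12) or np.any(self.area_km2 > cell_km2 + 1e-9):
            raise GridError("cell land area outside [0, cell area]")

    @property
    def total_km2(self) -> float:
        return float(self.area_km2.sum())

    def land_mask(self) -> np.ndarray:
        """Cells with any land at all."""
        return self.area_km2 > 0


def snap_to_cell(
    easting: float | np.ndarray, northing: float | np.ndarray, grid: GridSpec
) -> tuple[np.ndarray, np.ndarray]:
    """Map point coordinates to (row, col) of the containing half-open cell.

    Points exactly on an interior boundary belong to the cell whose
    lower-left corner they touch. Raises :class:`ExtentError` for points
    outside the grid.
    """
    e = np.asarray(easting, dtype=float)
    n = np.asarray(northing, dtype=float)
    col = np.floor((e - grid.origin_easting) / grid.resolution).astype(int)
    row = np.floor((n - grid.origin_northing) / grid.resolution).astype(int)
    bad = (col < 0) | (col >= grid.n_cols) | (row < 0) | (row >= grid.n_rows)
    if np.any(bad):
        raise ExtentError(
            f"{int(np.sum(bad))} point(s) outside grid extent {grid.extent}"
        )
    if np.isscalar(easting) and np.isscalar(northing):
        return int(row), int(col)
    return row, col


def _block_reduce_sum(fine_values: np.ndarray, factor: int) -> np.ndarray:
    r, c = fine_values.shape
    return (
        fine_values.reshape(r // factor, factor, c // factor, factor)
        .sum(axis=(1, 3))
    )


def land_area_map(land_mask_fine: RasterLayer, target: GridSpec) -> LandAreaRaster:
    """Aggregate a fine binary land mask to per-cell land area on ``target``.

    Each target cell's area is the count of land pixels it contains times the
    pixel area ``(fine_res/1000)^2`` km² (0.000625 km² for a 25 m mask). The
    fine grid must nest exactly in the target grid.
    """
    fine = land_mask_fine.grid
    if not target.nests(fine):
        raise AlignmentError(
            "land mask grid does not nest in target grid (origin/resolution/extent)"
        )
    factor = int(round(target.resolution / fine.resolution))
    mask = np.asarray(land_mask_fine.values, dtype=bool).astype(np.int64)
    counts = _block_reduce_sum(mask, factor)
    pixel_km2 = (fine.resolution / 1000.0) ** 2
    return LandAreaRaster(target, counts * pixel_km2)


def minmax_standardize(
    values: np.ndarray,
    companions: Sequence[float] = (),
    mask: np.ndarray | None = None,
) -> tuple[np.ndarray, list[float]]:
    """Affinely rescale ``values`` so the observed min maps to 0 and max to 1.

    The identical affine map is applied to ``companions`` (e.g. a suitability
    threshold measured on the same scale). Cells outside ``mask`` (or NaN)
    are left untouched. Raises :class:`DegenerateScaleError` when the masked
    values are constant.
    """
    values = np.asarray(values, dtype=float)
    if mask is None:
        mask = np.isfinite(values)
    else:
        mask = np.asarray(mask, dtype=bool) & np.isfinite(values)
    if mask.sum() < 2:
        raise DegenerateScaleError("need at least two finite values")
    lo = float(values[mask].min())
    hi = float(values[mask].max())
    if hi <= lo:
        raise DegenerateScaleError("constant field cannot be standardized")
    out = values.copy()
    out[mask] = (values[mask] - lo) / (hi - lo)
    scaled = [(float(c) - lo) / (hi - lo) for c in companions]
    return out, scaled


# ---------------------------------------------------------------------------
# GeoTIFF I/O (single band, planar metric CRS carried as an opaque tag)
# ---------------------------------------------------------------------------

def write_geotiff(path, layer: RasterLayer) -> None:
    """Write a single-band raster with ModelPixelScale/ModelTiepoint tags.

    The array is stored top-down (north row first) as GeoTIFF convention
    requires; metadata (kind, nodata, crs_tag, name) travels in the
    ImageDescription tag as JSON.
    """
    g = layer.grid
    res = float(g.resolution)
    top_northing = g.origin_northing + g.n_rows * res
    arr = np.flipud(np.asarray(layer.values))
    if arr.dtype == bool:
        arr = arr.astype(np.uint8)
    nodata = layer.nodata
    meta = {
        "kind": layer.kind,
        "nodata": None if (isinstance(nodata, float) and np.isnan(nodata)) else nodata,
        "nodata_is_nan": bool(isinstance(nodata, float) and np.isnan(nodata)),
        "crs_tag": g.crs_tag,
        "name": layer.name,
    }
    extratags = [
        (_TAG_MODEL_PIXEL_SCALE, "d", 3, (res, res, 0.0)),
        (_TAG_MODEL_TIEPOINT, "d", 6, (0.0, 0.0, 0.0, float(g.origin_easting), float(top_northing), 0.0)),
    ]
    tifffile.imwrite(
        path,
        arr,
        description=json.dumps(meta),
        extratags=extratags,
        photometric="minisblack",
    )


def read_geotiff(path) -> RasterLayer:
    """Read a raster written by :func:`write_geotiff` (or any single-band
    GeoTIFF carrying pixel-scale and tiepoint tags on a planar grid)."""
    with tifffile.TiffFile(path) as tif:
        page = tif.pages[0]
        arr = page.asarray()
        tags = page.tags
        try:
            sx, sy, _ = tags[_TAG_MODEL_PIXEL_SCALE].value[:3]
            tie = tags[_TAG_MODEL_TIEPOINT].value[:6]
        except KeyError as exc:  # pragma: no cover - malformed input
            raise GridError(f"{path}: missing GeoTIFF georeferencing tags") from exc
        desc = page.tags.get("ImageDescription")
        meta = {}
        if desc is not None:
            try:
                meta = json.loads(desc.value)
            except (TypeError, json.JSONDecodeError):
                meta = {}
    if abs(sx - sy) > 1e-9:
        raise GridError("non-square pixels are not supported")
    n_rows, n_cols = arr.shape
    origin_e = float(tie[3]) - float(tie[0]) * sx
    top_n = float(tie[4]) + float(tie[1]) * sy
    origin_n = top_n - n_rows * sy
    grid = GridSpec(
        origin_easting=origin_e,
        origin_northing=origin_n,
        resolution=float(sx),
        n_cols=n_cols,
        n_rows=n_rows,
        crs_tag=meta.get("crs_tag", "unknown"),
    )
    values = np.flipud(arr).copy()
    if meta.get("nodata_is_nan", False):
        nodata = np.nan
    else:
        nodata = meta.get("nodata")
        if nodata is None:
            nodata = np.nan
    return RasterLayer(
        grid,
        values,
        kind=meta.get("kind", "continuous"),
        nodata=nodata,
        name=meta.get("name", ""),
    )
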