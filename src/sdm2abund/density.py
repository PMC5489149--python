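"""Stage 2a — geo-referenced density polygons to per-cell density bounds.

Survey polygons are burned onto the fine land-mask grid (25 m in the field
protocol); where polygons overlap, the most recent survey wins (ties resolved
toward the larger density). Fine pixels are then aggregated to the working
grid under two assumptions that bracket the truth:

* **minimum** — unsurveyed land contributes zero to the cell mean, as if the
  survey covered all the habitat the species actually uses;
* **maximum** — unsurveyed land is representative of the surveyed pixels, so
  the cell takes the mean over surveyed pixels only.

Sea pixels never enter either denominator.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from shapely import contains_xy
from shapely.geometry import shape as shapely_shape
from shapely.geometry.base import BaseGeometry

from .grids import AlignmentError, GridSpec, RasterLayer
from .sdm import EnsembleSuitability

__all__ = [
    "DensityEstimate",
    "DensityRasterPair",
    "build_density_rasters",
    "extract_training_pairs",
    "read_density_geojson",
    "EmptyTrainingError",
]


class EmptyTrainingError(RuntimeError):
    """No surveyed cell sits above the presence threshold."""


@dataclass(frozen=True)
class DensityEstimate:
    """One published density estimate mapped to a representative polygon."""

    species: str
    polygon: BaseGeometry
    density: float  # individuals per km²
    year: int
    source: str = ""

    def __post_init__(self) -> None:
        if self.density < 0:
            raise ValueError("density must be non-negative")
        if not self.polygon.is_valid:
            raise ValueError("polygon is not valid")


@dataclass
class DensityRasterPair:
    """Minimum/maximum per-cell density bounds plus the surveyed fraction
    (share of each cell's land pixels covered by any survey)."""

    min_density: RasterLayer
    max_density: RasterLayer
    surveyed_fraction: RasterLayer


def build_density_rasters(
    estimates: list[DensityEstimate],
    grid: GridSpec,
    land_mask_fine: RasterLayer,
) -> DensityRasterPair:
    """Rasterize polygons at the fine land-mask resolution and aggregate to
    ``grid`` as min/max density bounds.

    A fine land pixel covered by several polygons takes the density of the
    most recent one; year ties go to the larger density (logged). Estimates
    covering no land pixel at all are dropped with a warning.
    """
    fine = land_mask_fine.grid
    if not grid.nests(fine):
        raise AlignmentError("working grid does not nest the fine land-mask grid")
    factor = int(round(grid.resolution / fine.resolution))
    land = np.asarray(land_mask_fine.values, dtype=bool)

    dens = np.full(fine.shape, np.nan)
    year = np.full(fine.shape, -np.inf)

    ee = fine.origin_easting + (np.arange(fine.n_cols) + 0.5) * fine.resolution
    nn = fine.origin_northing + (np.arange(fine.n_rows) + 0.5) * fine.resolution

    for est in estimates:
        minx, miny, maxx, maxy = est.polygon.bounds
        c0 = max(int(np.floor((minx - fine.origin_easting) / fine.resolution)), 0)
        c1 = min(int(np.ceil((maxx - fine.origin_easting) / fine.resolution)), fine.n_cols)
        r0 = max(int(np.floor((miny - fine.origin_northing) / fine.resolution)), 0)
        r1 = min(int(np.ceil((maxy - fine.origin_northing) / fine.resolution)), fine.n_rows)
        if c1 <= c0 or r1 <= r0:
            warnings.warn(f"density estimate outside grid dropped: {est.source or est.species}")
            continue
        sub_e, sub_n = np.meshgrid(ee[c0:c1], nn[r0:r1])
        inside = contains_xy(est.polygon, sub_e.ravel(), sub_n.ravel()).reshape(sub_e.shape)
        window = land[r0:r1, c0:c1] & inside
        if not window.any():
            warnings.warn(
                f"density estimate covers no land pixel, dropped: {est.source or est.species}"
            )
            continue
        yw = year[r0:r1, c0:c1]
        dw = dens[r0:r1, c0:c1]
        newer = window & (est.year > yw)
        tie = window & (est.year == yw)
        if tie.any():
            warnings.warn("overlapping surveys from the same year: larger density kept")
            with np.errstate(invalid="ignore"):
                newer |= tie & ~(dw >= est.density)
        yw[newer] = est.year
        dw[newer] = est.density

    surveyed = np.isfinite(dens)
    dens_filled = np.where(surveyed, dens, 0.0)

    def block(a):
        r, c = a.shape
        return a.reshape(r // factor, factor, c // factor, factor).sum(axis=(1, 3))

    n_land = block(land.astype(np.int64))
    n_surv = block(surveyed.astype(np.int64))
    sum_dens = block(dens_filled)

    with np.errstate(divide="ignore", invalid="ignore"):
        min_d = np.where(n_land > 0, sum_dens / np.maximum(n_land, 1), np.nan)
        max_d = np.where(n_surv > 0, sum_dens / np.maximum(n_surv, 1), np.nan)
        frac = np.where(n_land > 0, n_surv / np.maximum(n_land, 1), 0.0)
    min_d = np.where(n_surv > 0, min_d, np.nan)  # nodata where nothing surveyed

    return DensityRasterPair(
        min_density=RasterLayer(grid, min_d, nodata=np.nan, name="min_density"),
        max_density=RasterLayer(grid, max_d, nodata=np.nan, name="max_density"),
        surveyed_fraction=RasterLayer(grid, frac, nodata=np.nan, name="surveyed_fraction"),
    )


def extract_training_pairs(
    pair: DensityRasterPair, ensemble: EnsembleSuitability
) -> pd.DataFrame:
    """One row per surveyed cell predicted present (mean suitability at or
    above the mean threshold), with cell centroid coordinates.

    Raises :class:`EmptyTrainingError` when no surveyed cell survives, in
    which case the abundance stage cannot run.
    """
    grid = pair.min_density.grid
    if ensemble.mean_suitability.grid != grid:
        raise AlignmentError("suitability and density rasters are on different grids")
    surveyed = pair.surveyed_fraction.values > 0
    present = ensemble.presence_mask()
    keep = surveyed & present
    rows, cols = np.nonzero(keep)
    if rows.size == 0:
        raise EmptyTrainingError(
            "no surveyed cell lies above the suitability threshold"
        )
    ee, nn = grid.cell_centroids()
    return pd.DataFrame(
        {
            "row": rows,
            "col": cols,
            "suitability": ensemble.mean_suitability.values[rows, cols],
            "min_density": pair.min_density.values[rows, cols],
            "max_density": pair.max_density.values[rows, cols],
            "x": ee[rows, cols],
            "y": nn[rows, cols],
        }
    )


def read_density_geojson(path) -> list[DensityEstimate]:
    """Read a GeoJSON FeatureCollection with properties
    ``species, density_km2, year, source``."""
    with open(path) as fh:
        doc = json.load(fh)
    out = []
    for feat in doc.get("features", []):
        props = feat.get("properties", {})
        out.append(
            DensityEstimate(
                species=str(props["species"]),
                polygon=shapely_shape(feat["geometry"]),
                density=float(props["density_km2"]),
                year=int(props["year"]),
                source=str(props.get("source", "")),
            )
        )
    return out
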