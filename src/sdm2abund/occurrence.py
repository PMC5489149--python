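"""Occurrence record ingestion, plausibility QC and raster summaries.

Records arrive as grid references: the easting/northing name the lower-left
corner of a square whose side is the record's stated resolution (100 m, 1 km,
2 km or 10 km). QC discards records whose reference point falls outside the
land boundary buffered by that resolution class's positional uncertainty.
Kept records are summarised on a working grid as recording effort (count per
cell), binary occurrence, and the decade of the most recent sighting.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
from shapely.geometry.base import BaseGeometry
from shapely.prepared import prep

from .grids import GridSpec, RasterLayer, snap_to_cell

__all__ = [
    "OccurrenceRecord",
    "OccurrenceMaps",
    "VALID_RESOLUTIONS",
    "DEFAULT_YEAR_WINDOW",
    "ValidationError",
    "validate_records",
    "filter_by_resolution",
    "build_occurrence_maps",
    "read_records_csv",
    "write_discard_log",
]

VALID_RESOLUTIONS = (100, 1000, 2000, 10000)
DEFAULT_YEAR_WINDOW = (1960, 2015)

CSV_HEADER = ["species", "easting", "northing", "resolution_m", "year"]


class ValidationError(ValueError):
    """A record carries an unusable resolution class or malformed field."""


@dataclass(frozen=True)
class OccurrenceRecord:
    """One sighting, georeferenced as a square of side ``resolution`` metres
    with lower-left corner at (easting, northing)."""

    species: str
    easting: float
    northing: float
    resolution: int
    year: int


@dataclass
class OccurrenceMaps:
    """Raster summaries of a species' kept records on one working grid."""

    effort: RasterLayer       # record count per cell
    occurrence: RasterLayer   # 1 where effort > 0
    last_decade: RasterLayer  # decade of most recent record; nodata elsewhere


def validate_records(
    records: Iterable[OccurrenceRecord],
    land_boundary: BaseGeometry,
    buffer_per_resolution: dict[int, float] | None = None,
    year_window: tuple[int, int] = DEFAULT_YEAR_WINDOW,
) -> tuple[list[OccurrenceRecord], list[tuple[OccurrenceRecord, str]]]:
    """Resolution-aware plausibility QC.

    A record is kept iff its reference point lies inside the land boundary
    buffered by its own resolution class's distance (default: the resolution
    itself, i.e. the positional uncertainty of the grid reference). Records
    outside the configured year window or with coordinates that are not
    multiples of their resolution are discarded with a reason code. A record
    with a resolution outside the recognised classes raises
    :class:`ValidationError`.

    Returns ``(kept, discards)`` where discards are ``(record, reason)``
    pairs with reasons in ``{"outside_buffered_boundary", "year_out_of_window",
    "misaligned_reference"}``.
    """
    from shapely.geometry import Point

    if buffer_per_resolution is None:
        buffer_per_resolution = {r: float(r) for r in VALID_RESOLUTIONS}
    records = list(records)
    unknown = {r.resolution for r in records} - set(buffer_per_resolution)
    if unknown:
        raise ValidationError(f"unknown resolution class(es): {sorted(unknown)}")

    buffered = {
        res: prep(land_boundary.buffer(dist))
        for res, dist in buffer_per_resolution.items()
        if any(r.resolution == res for r in records)
    }
    kept: list[OccurrenceRecord] = []
    discards: list[tuple[OccurrenceRecord, str]] = []
    y0, y1 = year_window
    for rec in records:
        if not (y0 <= rec.year <= y1):
            discards.append((rec, "year_out_of_window"))
            continue
        if rec.easting % rec.resolution or rec.northing % rec.resolution:
            discards.append((rec, "misaligned_reference"))
            continue
        if not buffered[rec.resolution].covers(Point(rec.easting, rec.northing)):
            discards.append((rec, "outside_buffered_boundary"))
            continue
        kept.append(rec)
    return kept, discards


def filter_by_resolution(
    records: Sequence[OccurrenceRecord], working_resolution: int
) -> list[OccurrenceRecord]:
    """Keep only records whose stated resolution is at least as fine as the
    working grid, so every kept record carries equivalent (or better)
    positional uncertainty: at 1 km only 100 m and 1 km records survive; at
    10 km all four classes do."""
    if working_resolution not in (1000, 10000):
        raise ValidationError(
            f"working resolution must be 1000 or 10000 m, got {working_resolution}"
        )
    return [r for r in records if r.resolution <= working_resolution]


def build_occurrence_maps(
    records: Sequence[OccurrenceRecord], grid: GridSpec
) -> OccurrenceMaps:
    """Rasterize kept records into effort / occurrence / last-decade layers.

    Records must already be validated and resolution-filtered for this grid,
    so each record's square falls inside a single cell (its reference point
    is snapped). The decade of a record is ``floor(year/10)*10``.
    """
    effort = np.zeros(grid.shape, dtype=np.int64)
    last_year = np.full(grid.shape, -1, dtype=np.int64)
    if records:
        e = np.array([r.easting for r in records], dtype=float)
        n = np.array([r.northing for r in records], dtype=float)
        years = np.array([r.year for r in records], dtype=np.int64)
        rows, cols = snap_to_cell(e, n, grid)
        np.add.at(effort, (rows, cols), 1)
        np.maximum.at(last_year, (rows, cols), years)
    occurrence = (effort > 0).astype(np.int8)
    decade = np.where(last_year >= 0, (last_year // 10) * 10, -1).astype(np.int64)
    return OccurrenceMaps(
        effort=RasterLayer(grid, effort, kind="continuous", nodata=-1, name="effort"),
        occurrence=RasterLayer(grid, occurrence, kind="binary", nodata=-1, name="occurrence"),
        last_decade=RasterLayer(grid, decade, kind="categorical", nodata=-1, name="last_decade"),
    )


def read_records_csv(path) -> list[OccurrenceRecord]:
    """Read records from a CSV with header
    ``species,easting,northing,resolution_m,year``."""
    out: list[OccurrenceRecord] = []
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh)
        missing = set(CSV_HEADER) - set(reader.fieldnames or [])
        if missing:
            raise ValidationError(f"records CSV missing columns: {sorted(missing)}")
        for row in reader:
            out.append(
                OccurrenceRecord(
                    species=row["species"],
                    easting=float(row["easting"]),
                    northing=float(row["northing"]),
                    resolution=int(row["resolution_m"]),
                    year=int(row["year"]),
                )
            )
    return out


def write_discard_log(path, discards: Sequence[tuple[OccurrenceRecord, str]]) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(CSV_HEADER + ["reason"])
        for rec, reason in discards:
            writer.writerow(
                [rec.species, rec.easting, rec.northing, rec.resolution, rec.year, reason]
            )
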