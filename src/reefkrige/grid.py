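"""The 0.04-degree analysis grid: reef cells, regions, rasterisation of reports.

Every grid cell that contains any mapped reef counts as a reef cell,
regardless of reef type.  Cell membership uses half-open cells
``[edge, edge + resolution)`` anchored at a configurable origin (default
(-90, -180), aligned with the Coral Reef Watch convention), with longitudes
normalised modulo 360 relative to the origin so that Pacific domains are
contiguous across the antimeridian.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: Severity codes that constitute bleaching "presence" (moderate/severe, >10%).
PRESENCE_SEVERITIES = (2, 3)


@dataclass(frozen=True)
class RegionSpec:
    """A kriging region: a lat/lon box, possibly crossing the antimeridian.

    ``lon_min``/``lon_max`` are in degrees; the interval is interpreted
    going eastward from ``lon_min`` to ``lon_max`` (mod 360), so
    ``lon_min=120, lon_max=-120`` spans the central Pacific.
    ``overlap_km`` records the nominal overlap with sibling sections
    (used for the three-way Pacific split).
    """

    name: str
    lat_min: float
    lat_max: float
    lon_min: float
    lon_max: float
    overlap_km: float = 0.0

    def contains(self, lat, lon):
        lat = np.asarray(lat, dtype=float)
        lon = np.asarray(lon, dtype=float)
        span = (self.lon_max - self.lon_min) % 360.0
        if span == 0.0:
            span = 360.0
        rel = (lon - self.lon_min) % 360.0
        return (lat >= self.lat_min) & (lat <= self.lat_max) & (rel <= span)


def default_regions() -> list[RegionSpec]:
    """The four analysis domains, with the main Pacific in three sections.

    The three Pacific sections overlap by 12 degrees of longitude
    (>= 1000 km everywhere equatorward of 30 degrees latitude); kriged
    probabilities in the overlaps are averaged downstream to remove edge
    effects of the split.
    """
    return [
        RegionSpec("caribbean", 5.0, 35.0, -100.0, -55.0),
        RegionSpec("indian", -35.0, 32.0, 30.0, 105.0),
        RegionSpec("east_pacific", -25.0, 5.0, -120.0, -75.0),
        RegionSpec("pacific_west", -32.0, 32.0, 105.0, 164.0, overlap_km=1000.0),
        RegionSpec("pacific_central", -32.0, 32.0, 152.0, 208.0, overlap_km=1000.0),
        RegionSpec("pacific_east", -32.0, 32.0, 196.0, 250.0, overlap_km=1000.0),
    ]


@dataclass
class ReefGrid:
    """Cell table of an equal-angle analysis grid.

    ``cells`` is indexed by integer ``cell_id`` with columns
    ``row, col, lat, lon, reef_area, region`` (lat/lon are cell centres,
    reef_area in km^2).  ``land_cells`` lists cell ids known to be land
    (neither reef nor ocean); reports that fall there are "bleaching
    reported on land" and are rejected by QC.
    """

    cells: pd.DataFrame
    origin: tuple[float, float] = (-90.0, -180.0)
    resolution: float = 0.04
    land_cells: frozenset = field(default_factory=frozenset)

    def __post_init__(self):
        if self.resolution <= 0:
            raise ValueError("resolution must be positive")
        if len(self.cells) and (self.cells["reef_area"] < 0).any():
            raise ValueError("reef_area must be non-negative")

    @property
    def ncols(self) -> int:
        return int(round(360.0 / self.resolution))

    def cell_index(self, lat, lon):
        """Map coordinates to integer cell ids (vectorised).

        row = floor((lat - lat0)/res); col = floor(((lon - lon0) mod 360)/res);
        cells are half-open so a point exactly on the south/west edge belongs
        to that cell.
        """
        lat = np.asarray(lat, dtype=float)
        lon = np.asarray(lon, dtype=float)
        lat0, lon0 = self.origin
        res = self.resolution
        # 1e-9 cell-units guard so exact edges land in the cell to their east/north
        # despite floating rounding of (lat - lat0)/res.
        row = np.floor((lat - lat0) / res + 1e-9).astype(np.int64)
        col = np.floor(((lon - lon0) % 360.0) / res + 1e-9).astype(np.int64)
        col = np.clip(col, 0, self.ncols - 1)
        return row * self.ncols + col

    def cell_centre(self, cell_id):
        """Centre lat/lon of arbitrary (not necessarily reef) cell ids."""
        cell_id = np.asarray(cell_id, dtype=np.int64)
        lat0, lon0 = self.origin
        row, col = cell_id // self.ncols, cell_id % self.ncols
        lat = lat0 + (row + 0.5) * self.resolution
        lon = lon0 + (col + 0.5) * self.resolution
        lon = (lon + 180.0) % 360.0 - 180.0
        return lat, lon

    @property
    def reef_cell_ids(self) -> np.ndarray:
        return self.cells.index.to_numpy()

    def is_reef(self, cell_id):
        return np.isin(np.asarray(cell_id), self.cells.index.to_numpy())

    def reef_area_of(self, cell_ids) -> float:
        """Total reef area (km^2) of a set of reef cells."""
        ids = np.asarray(list(cell_ids), dtype=np.int64)
        if ids.size == 0:
            return 0.0
        missing = ids[~np.isin(ids, self.cells.index.to_numpy())]
        if missing.size:
            raise KeyError(f"unknown cell ids: {missing[:5].tolist()}")
        return float(self.cells.loc[ids, "reef_area"].sum())

    def region_cells(self, region: RegionSpec) -> pd.DataFrame:
        mask = region.contains(self.cells["lat"].to_numpy(), self.cells["lon"].to_numpy())
        return self.cells.loc[mask]


def presence_cells(reports: pd.DataFrame, year: int, grid: ReefGrid) -> pd.DataFrame:
    """Indicator-1 points: cells with >=1 in-year report of severity 2 or 3.

    Reports of severity -1/0/1 never create presence; multiple qualifying
    reports in one cell collapse to a single point.  Returns a frame with
    columns ``cell_id, lat, lon, year, indicator``.
    """
    sel = reports[(reports["year"] == year) & reports["severity_code"].isin(PRESENCE_SEVERITIES)]
    if len(sel) == 0:
        return _empty_points()
    ids = np.unique(grid.cell_index(sel["latitude"].to_numpy(), sel["longitude"].to_numpy()))
    lat, lon = grid.cell_centre(ids)
    return pd.DataFrame(
        {"cell_id": ids, "lat": lat, "lon": lon, "year": year, "indicator": np.ones(len(ids), dtype=int)}
    )


def pseudo_absence_cells(annual_max: pd.Series, grid: ReefGrid, year: int) -> tuple[pd.DataFrame, list[int]]:
    """Indicator-0 points: reef cells whose annual maximum DHW is zero.

    ``annual_max`` is indexed by reef cell_id (degC-weeks for the given
    year).  A cell may legitimately carry both a presence point and a
    pseudo-absence point for the same year.  Reef cells with no DHW value
    are excluded and returned in the second element for logging.
    """
    reef_ids = grid.reef_cell_ids
    have = annual_max.reindex(reef_ids)
    missing = [int(c) for c in reef_ids[have.isna().to_numpy()]]
    zero = have[have == 0.0].index.to_numpy()
    if zero.size == 0:
        return _empty_points(), missing
    lat, lon = grid.cell_centre(zero)
    pts = pd.DataFrame(
        {"cell_id": zero, "lat": lat, "lon": lon, "year": year, "indicator": np.zeros(len(zero), dtype=int)}
    )
    return pts, missing


def _empty_points() -> pd.DataFrame:
    return pd.DataFrame(
        {
            "cell_id": pd.Series(dtype=np.int64),
            "lat": pd.Series(dtype=float),
            "lon": pd.Series(dtype=float),
            "year": pd.Series(dtype=int),
            "indicator": pd.Series(dtype=int),
        }
    )
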