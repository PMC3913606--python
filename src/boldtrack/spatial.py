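"""Bathymetric habitat classification and fishery discarding-zone overlap.

Habitat follows the standard marine classes for this shelf system: *shelf*
(< 200 m), *shelf edge* (200–2000 m, closed interval) and *oceanic*
(> 2000 m).  Fishery exposure is modelled through discarding zones: a 19 km
radius around each longline's final hauling point, active from the end of
hauling for one hour — the period when offal discarding (and albatross
aggregation) happens.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .tracks import Trip, haversine_km

logger = logging.getLogger(__name__)

SHELF_MAX_M = 200.0
OCEANIC_MIN_M = 2000.0

HABITAT_ORDER = ["shelf", "shelf_edge", "oceanic"]

FISHING_COLUMNS = [
    "line_id", "set_start", "set_end", "haul_start", "haul_end",
    "set_lat", "set_lon", "haul_lat", "haul_lon",
]


class BathymetryFormatError(ValueError):
    pass


@dataclass
class BathymetryGrid:
    """Regular lat/lon depth grid (metres, positive downward).

    Row 0 is the northernmost row, matching ESRI ASCII ordering.
    """

    xllcorner: float  # lon of lower-left corner
    yllcorner: float  # lat of lower-left corner
    cellsize: float  # degrees
    depth: np.ndarray  # (nrows, ncols), NaN = nodata
    nodata: float = -9999.0

    @property
    def nrows(self) -> int:
        return self.depth.shape[0]

    @property
    def ncols(self) -> int:
        return self.depth.shape[1]

    def depth_at(self, lat: float, lon: float) -> float:
        """Nearest-cell depth (m); NaN for nodata cells.

        Ties at cell boundaries resolve to the lower row/column index.  Out
        of bounds raises, naming the point.
        """
        col = (np.asarray(lon) - self.xllcorner) / self.cellsize
        row_from_bottom = (np.asarray(lat) - self.yllcorner) / self.cellsize
        # cell centres sit at k + 0.5; a point on the boundary between two
        # cells (integer offset u) is equidistant and resolves to the lower
        # *stored* index: column u - 1, and the more northern row (rows are
        # stored north-first, so that is floor(u) from the bottom).
        ci = np.where(col == np.floor(col), col - 1, np.floor(col)).astype(int)
        ri_bot = np.floor(row_from_bottom).astype(int)
        ci = np.where((col >= 0) & (ci < 0), 0, ci)
        ri_bot = np.where(row_from_bottom == self.nrows, self.nrows - 1, ri_bot)
        if np.any((ci < 0) | (ci >= self.ncols) | (ri_bot < 0) | (ri_bot >= self.nrows)):
            raise ValueError(f"point (lat={lat}, lon={lon}) outside bathymetry bounds")
        ri = self.nrows - 1 - ri_bot
        return self.depth[ri, ci]


def read_bathymetry(path) -> BathymetryGrid:
    """Read an ESRI ASCII grid (.asc) of depths in metres."""
    header: dict[str, float] = {}
    rows: list[np.ndarray] = []
    with open(path) as fh:
        for line in fh:
            parts = line.split()
            if not parts:
                continue
            key = parts[0].lower()
            if key in {"ncols", "nrows", "xllcorner", "yllcorner", "cellsize",
                       "nodata_value"} and len(parts) == 2:
                header[key] = float(parts[1])
            else:
                rows.append(np.array(parts, dtype=float))
    required = {"ncols", "nrows", "xllcorner", "yllcorner", "cellsize"}
    if not required <= header.keys():
        raise BathymetryFormatError(
            f"{path}: missing header field(s) {sorted(required - header.keys())}"
        )
    ncols, nrows = int(header["ncols"]), int(header["nrows"])
    data = np.concatenate(rows) if rows else np.empty(0)
    if data.size != nrows * ncols:
        raise BathymetryFormatError(
            f"{path}: expected {nrows * ncols} values, found {data.size}"
        )
    depth = data.reshape(nrows, ncols)
    nodata = header.get("nodata_value", -9999.0)
    depth = np.where(depth == nodata, np.nan, depth)
    return BathymetryGrid(
        xllcorner=header["xllcorner"],
        yllcorner=header["yllcorner"],
        cellsize=header["cellsize"],
        depth=depth,
        nodata=nodata,
    )


def write_bathymetry(grid: BathymetryGrid, path) -> None:
    with open(path, "w") as fh:
        fh.write(f"ncols {grid.ncols}\n")
        fh.write(f"nrows {grid.nrows}\n")
        fh.write(f"xllcorner {float(grid.xllcorner)!r}\n")
        fh.write(f"yllcorner {float(grid.yllcorner)!r}\n")
        fh.write(f"cellsize {float(grid.cellsize)!r}\n")
        fh.write(f"NODATA_value {float(grid.nodata)!r}\n")
        out = np.where(np.isnan(grid.depth), grid.nodata, grid.depth)
        for row in out:
            fh.write(" ".join(repr(float(v)) for v in row) + "\n")


def depth_at(grid: BathymetryGrid, lat: float, lon: float) -> float:
    return grid.depth_at(lat, lon)


def classify_habitat(depth_m) -> str | None:
    """Map a depth to shelf / shelf_edge / oceanic.

    Depths of exactly 200 m and 2000 m belong to the shelf edge ("between
    200 m and 2000 m" read as a closed interval).  Missing depth -> None,
    excluded from models with a log entry.
    """
    if depth_m is None or (np.isscalar(depth_m) and np.isnan(depth_m)):
        logger.info("missing depth: habitat class unavailable")
        return None
    if depth_m < 0:
        raise ValueError(f"negative depth {depth_m} m")
    if depth_m < SHELF_MAX_M:
        return "shelf"
    if depth_m <= OCEANIC_MIN_M:
        return "shelf_edge"
    return "oceanic"


def read_fishing_csv(path) -> pd.DataFrame:
    """Read the longline set/haul event table."""
    df = pd.read_csv(path)
    missing = [c for c in FISHING_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing column(s) {missing}")
    for col in ("set_start", "set_end", "haul_start", "haul_end"):
        df[col] = pd.to_datetime(df[col], utc=True, format="ISO8601")
    bad = ~(
        (df["set_start"] < df["set_end"])
        & (df["set_end"] <= df["haul_start"])
        & (df["haul_start"] < df["haul_end"])
    )
    if bad.any():
        raise ValueError(
            f"{path}: {int(bad.sum())} event(s) violate set_start < set_end <= "
            "haul_start < haul_end"
        )
    return df


@dataclass(frozen=True)
class DiscardingZone:
    """Spatiotemporal buffer where a vessel may be discarding offal."""

    line_id: str
    centre: tuple[float, float]  # haul-end position
    radius_km: float
    window: tuple[pd.Timestamp, pd.Timestamp]  # [haul_end, haul_end + window_h]


def build_discarding_zones(
    events: pd.DataFrame, radius_km: float = 19.0, window_h: float = 1.0
) -> list[DiscardingZone]:
    """One zone per longline event, centred on the end-of-hauling point."""
    zones = []
    for _, row in events.iterrows():
        t0 = row["haul_end"]
        zones.append(
            DiscardingZone(
                line_id=str(row["line_id"]),
                centre=(float(row["haul_lat"]), float(row["haul_lon"])),
                radius_km=radius_km,
                window=(t0, t0 + pd.Timedelta(hours=window_h)),
            )
        )
    return zones


def fix_overlap(lat: float, lon: float, t: pd.Timestamp, zones: list[DiscardingZone]) -> bool:
    """True iff the fix falls inside any zone's radius and time window
    (both closed)."""
    for z in zones:
        if z.window[0] <= t <= z.window[1] and haversine_km((lat, lon), z.centre) <= z.radius_km:
            return True
    return False


def overlap_flags(trip: Trip, zones: list[DiscardingZone]) -> np.ndarray:
    """Vectorised per-fix overlap for one trip."""
    n = len(trip.fixes)
    flags = np.zeros(n, dtype=bool)
    if not zones:
        return flags
    lat = trip.fixes["lat"].to_numpy()
    lon = trip.fixes["lon"].to_numpy()
    t = trip.fixes["timestamp"]
    for z in zones:
        in_time = ((t >= z.window[0]) & (t <= z.window[1])).to_numpy()
        if not in_time.any():
            continue
        d = haversine_km((lat[in_time], lon[in_time]), z.centre)
        sub = np.flatnonzero(in_time)
        flags[sub[d <= z.radius_km]] = True
    return flags


def trip_overlap_summary(trip: Trip, zones: list[DiscardingZone]):
    """(any_overlap, proportion of fixes overlapping, hours at vessels)."""
    flags = overlap_flags(trip, zones)
    prop = float(flags.mean()) if len(flags) else 0.0
    return bool(flags.any()), prop, prop * trip.duration_h


def summarise_overlap(summary: pd.DataFrame) -> dict:
    """Population-level fishery bookkeeping from a per-trip overlap table
    (columns: trip_id, bird_id, any_overlap, prop_fixes).

    Returns trip- and bird-level overlap percentages and the mean
    percentage of time at vessels among trips that overlapped at least
    once — the standard way tracking studies report fishery association.
    """
    n_trips = len(summary)
    n_overlap = int(summary["any_overlap"].sum())
    birds = summary.groupby("bird_id")["any_overlap"].any()
    overlapping = summary.loc[summary["any_overlap"], "prop_fixes"]
    return {
        "n_trips": n_trips,
        "trips_overlapping": n_overlap,
        "pct_trips_overlapping": 100.0 * n_overlap / n_trips if n_trips else 0.0,
        "n_birds": int(birds.size),
        "birds_overlapping": int(birds.sum()),
        "pct_birds_overlapping": float(100.0 * birds.mean()) if len(birds) else 0.0,
        "mean_pct_time_at_vessels_overlapping_trips": float(100.0 * overlapping.mean())
        if n_overlap else 0.0,
    }
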