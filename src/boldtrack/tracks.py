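"""GPS ingestion, trip segmentation and trip-level foraging metrics.

Fixes are WGS84 decimal degrees (south and west negative) with UTC
timestamps.  A *trip* is a maximal run of consecutive fixes further than a
colony buffer (default 2 km) from the colony; points inside the buffer are
treated as time at the nest and excluded from all at-sea analyses.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

EARTH_RADIUS_KM = 6371.0

GPS_COLUMNS = ["bird_id", "timestamp", "lat", "lon"]

PHASES = ("incubation", "brooding")


def haversine_km(p1, p2):
    """Great-circle distance between two (lat, lon) points in km.

    Accepts scalars or broadcastable arrays; spherical Earth of radius
    6371.0 km.
    """
    lat1, lon1 = np.radians(p1[0]), np.radians(p1[1])
    lat2, lon2 = np.radians(p2[0]), np.radians(p2[1])
    dlat = lat2 - lat1
    dlon = lon2 - lon1
    a = np.sin(dlat / 2.0) ** 2 + np.cos(lat1) * np.cos(lat2) * np.sin(dlon / 2.0) ** 2
    return 2.0 * EARTH_RADIUS_KM * np.arcsin(np.sqrt(np.clip(a, 0.0, 1.0)))


@dataclass
class Trip:
    """One colony-to-colony foraging excursion.

    ``fixes`` is a DataFrame with columns ``timestamp`` (tz-aware UTC),
    ``lat``, ``lon`` and, once :func:`compute_speeds` has run, ``speed_kmh``.
    """

    trip_id: str
    bird_id: str
    fixes: pd.DataFrame
    phase: str | None = None
    complete: bool = False
    usable_for_fpt: bool = field(default=True)

    def __len__(self):
        return len(self.fixes)

    @property
    def duration_h(self) -> float:
        t = self.fixes["timestamp"]
        return (t.iloc[-1] - t.iloc[0]).total_seconds() / 3600.0


@dataclass(frozen=True)
class TripMetrics:
    """The four foraging-effort indices collapsed by the trip-metric PCA."""

    trip_id: str
    bird_id: str
    duration_h: float
    max_range_km: float
    max_lat_north: float  # maximum signed latitude attained (deg)
    max_lat_south: float  # |minimum signed latitude| attained (deg)


class GPSFormatError(ValueError):
    pass


def read_gps_csv(path) -> pd.DataFrame:
    """Read a logger CSV into a per-bird time-sorted fix table.

    Required columns: ``bird_id, timestamp, lat, lon`` (a ``trip_id`` column
    and any extras are carried through).  Duplicate timestamps within a bird
    keep the first occurrence with a logged warning; unparseable timestamps
    raise with the offending line numbers.
    """
    df = pd.read_csv(path)
    missing = [c for c in GPS_COLUMNS if c not in df.columns]
    if missing:
        raise GPSFormatError(f"{path}: missing required column(s) {missing}")
    ts = pd.to_datetime(df["timestamp"], utc=True, format="ISO8601", errors="coerce")
    bad = np.flatnonzero(ts.isna() & df["timestamp"].notna())
    if len(bad):
        lines = (bad + 2)[:5].tolist()  # +2: header + 1-indexing
        raise GPSFormatError(f"{path}: unparseable timestamp at line(s) {lines}")
    df = df.assign(timestamp=ts)
    df = df.sort_values(["bird_id", "timestamp"], kind="stable").reset_index(drop=True)
    dup = df.duplicated(subset=["bird_id", "timestamp"])
    if dup.any():
        logger.warning("%s: dropped %d duplicate bird/timestamp fixes", path, int(dup.sum()))
        df = df[~dup].reset_index(drop=True)
    for col, lo, hi in [("lat", -90, 90), ("lon", -180, 180)]:
        if not df[col].between(lo, hi).all():
            raise GPSFormatError(f"{path}: {col} outside [{lo}, {hi}]")
    return df


def dist_to_colony_km(df: pd.DataFrame, colony) -> np.ndarray:
    return haversine_km((df["lat"].to_numpy(), df["lon"].to_numpy()), colony)


def segment_trips(
    fixes: pd.DataFrame,
    colony,
    buffer_km: float = 2.0,
    min_fixes: int = 5,
    phases: dict | None = None,
) -> list[Trip]:
    """Cut each bird's fix series into trips at the colony buffer.

    A trip is a maximal run of consecutive fixes with distance-to-colony
    > ``buffer_km``.  Runs shorter than ``min_fixes`` are dropped as GPS
    jitter.  ``complete`` is set when the run is flanked by inside-buffer
    fixes on both sides.  ``phases`` optionally maps (bird_id, trip ordinal
    within bird) or bird_id to a phase label; a ``phase`` column in
    ``fixes``, if present, takes precedence.
    """
    trips: list[Trip] = []
    for bird_id, sub in fixes.groupby("bird_id", sort=True):
        sub = sub.reset_index(drop=True)
        away = dist_to_colony_km(sub, colony) > buffer_km
        # run starts/ends of `away`
        padded = np.concatenate([[False], away, [False]])
        starts = np.flatnonzero(~padded[:-1] & padded[1:])
        ends = np.flatnonzero(padded[:-1] & ~padded[1:])
        ordinal = 0
        for s, e in zip(starts, ends):
            if e - s < min_fixes:
                continue
            ordinal += 1
            trip_fixes = sub.iloc[s:e].reset_index(drop=True)
            complete = s > 0 and e < len(sub)
            gaps = trip_fixes["timestamp"].diff().dt.total_seconds().iloc[1:]
            if (gaps > 3600).any():
                logger.warning(
                    "bird %s trip %d: %d inter-fix gap(s) > 1 h", bird_id, ordinal,
                    int((gaps > 3600).sum()),
                )
            phase = None
            if "phase" in trip_fixes.columns:
                phase = trip_fixes["phase"].iloc[0]
            elif phases is not None:
                phase = phases.get((bird_id, ordinal), phases.get(bird_id))
            trips.append(
                Trip(
                    trip_id=f"{bird_id}_t{ordinal}",
                    bird_id=str(bird_id),
                    fixes=trip_fixes,
                    phase=phase,
                    complete=complete,
                )
            )
    return trips


def compute_speeds(trip: Trip) -> Trip:
    """Attach per-fix ground speed (km/h); fix 0 inherits fix 1's speed."""
    df = trip.fixes
    if len(df) < 2:
        raise ValueError(f"trip {trip.trip_id}: need >= 2 fixes to compute speeds")
    lat = df["lat"].to_numpy()
    lon = df["lon"].to_numpy()
    dt_s = df["timestamp"].diff().dt.total_seconds().to_numpy()[1:]
    if np.any(dt_s <= 0):
        raise ValueError(f"trip {trip.trip_id}: non-positive time step between fixes")
    step_km = haversine_km((lat[:-1], lon[:-1]), (lat[1:], lon[1:]))
    speed = np.empty(len(df))
    speed[1:] = step_km / (dt_s / 3600.0)
    speed[0] = speed[1]
    return replace(trip, fixes=df.assign(speed_kmh=speed))


def filter_on_water(trip: Trip, threshold_kmh: float = 10.0) -> Trip:
    """Drop fixes slower than ``threshold_kmh`` (birds sitting on the water).

    Returns a new Trip; if nothing survives the filter the result is flagged
    unusable for FPT analysis.
    """
    if "speed_kmh" not in trip.fixes.columns:
        trip = compute_speeds(trip)
    keep = trip.fixes["speed_kmh"] >= threshold_kmh
    out = replace(trip, fixes=trip.fixes[keep].reset_index(drop=True))
    out.usable_for_fpt = int(keep.sum()) >= 2
    return out


def trip_metrics(trip: Trip, colony) -> TripMetrics:
    """Duration, foraging range and signed-latitude extents of one trip."""
    lat = trip.fixes["lat"].to_numpy()
    d = dist_to_colony_km(trip.fixes, colony)
    return TripMetrics(
        trip_id=trip.trip_id,
        bird_id=trip.bird_id,
        duration_h=trip.duration_h,
        max_range_km=float(d.max()),
        max_lat_north=float(lat.max()),
        max_lat_south=float(abs(lat.min())),
    )


def filter_phase(trips: list[Trip], phase: str = "brooding", strict: bool = True) -> list[Trip]:
    """Keep trips of one breeding phase (incubation trips are much longer
    and are excluded from the foraging-personality analysis)."""
    if phase not in PHASES:
        raise ValueError(f"unknown phase {phase!r}; expected one of {PHASES}")
    unlabelled = [t for t in trips if t.phase is None]
    if unlabelled:
        if strict:
            raise ValueError(
                f"{len(unlabelled)} trip(s) lack a phase label (first: "
                f"{unlabelled[0].trip_id}); pass strict=False to keep them"
            )
        logger.warning("%d unlabelled trip(s) retained (strict=False)", len(unlabelled))
        return [t for t in trips if t.phase in (None, phase)]
    bad = {t.phase for t in trips} - set(PHASES)
    if bad:
        raise ValueError(f"unknown phase label(s) {sorted(bad)}")
    return [t for t in trips if t.phase == phase]


def metrics_table(trips: list[Trip], colony) -> pd.DataFrame:
    """Trip-metric table (one row per trip) ready for the foraging PCA."""
    rows = [trip_metrics(t, colony) for t in trips]
    return pd.DataFrame(
        {
            "trip_id": [m.trip_id for m in rows],
            "bird_id": [m.bird_id for m in rows],
            "duration_h": [m.duration_h for m in rows],
            "max_range_km": [m.max_range_km for m in rows],
            "max_lat_north": [m.max_lat_north for m in rows],
            "max_lat_south": [m.max_lat_south for m in rows],
        }
    )
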