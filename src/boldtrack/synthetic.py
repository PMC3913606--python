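"""Synthetic study generator with known ground truth.

No field data ship with this package, so every pipeline input — GPS tracks,
bathymetry, longline fishing events, novel-object behaviour counts,
breeding histories and yearly SSTa — is simulated with planted, recorded
signal (patch locations, latent repeatability, fledging-model
coefficients).  Each downstream stage therefore has a recovery test against
a known truth.

Movement is a two-state correlated random walk: fast, directionally
persistent commuting between the colony and planted prey patches, and
slow, sinuous searching inside patches — the commute/forage structure that
first-passage-time analysis is designed to resolve.  Geometry is computed
on a local tangent plane around the colony (kilometres east/north) and
converted to WGS84 degrees for output.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .tracks import EARTH_RADIUS_KM

KM_PER_DEG_LAT = np.pi * EARTH_RADIUS_KM / 180.0  # ~111.19 km

# SSTa tercile ranges (deg C) of year quality; years are drawn uniformly
# within a band, with bands balanced across the study period
SSTA_BANDS = {"low": (-0.60, -0.36), "medium": (-0.36, -0.15), "high": (-0.15, 0.13)}


@dataclass
class FledgingEffects:
    """Log-odds coefficients of the planted breeding-success model
    (sex coded female=0 / male=1; score and SSTa continuous)."""

    intercept: float = 0.3
    score: float = 0.0
    sex: float = 0.0
    ssta: float = 0.8
    score_sex: float = 0.0
    score_ssta: float = 0.0
    sex_ssta: float = 0.0
    score_sex_ssta: float = 0.0


@dataclass
class SimConfig:
    """Study-design parameters for the synthetic colony.

    Defaults mirror the field design: colony at 48.4°S 68.4°E, fixes every
    2 minutes, brooding trips to patches on/near the shelf edge, 59 focal
    birds followed over 23 breeding seasons, ~10% of behaviour-tested birds
    retested.
    """

    seed: int = 0
    colony: tuple[float, float] = (-48.4, 68.4)
    n_birds: int = 59
    trips_per_bird: int = 2
    fix_interval_s: float = 120.0
    patch_count: int = 1  # planted patches per trip
    patch_radius_km: float = 5.0
    patch_distance_km: tuple[float, float] = (60.0, 350.0)
    patch_dwell_h: float = 5.0
    commute_speed_kmh: float = 45.0
    forage_speed_kmh: float = 15.0
    turn_concentration_commute: float = 60.0  # von Mises kappa
    turn_concentration_forage: float = 1.0
    icc_boldness: float = 0.5
    retest_fraction: float = 0.10
    sex_ratio: float = 0.5  # proportion male
    # between-bird consistency in where birds forage: each bird has a
    # preferred patch distance and bearing; trips scatter around them
    trip_distance_sd_km: float = 80.0
    trip_bearing_sd_deg: float = 30.0
    # boldness/foraging syndrome: bolder birds prefer patches nearer the
    # colony (negative cross-context correlation on the latent scale)
    syndrome_strength: float = 0.4
    years: int = 23
    shelf_km: float = 100.0  # distance at which depth reaches 200 m
    shelf_break_km: float = 300.0  # distance at which depth reaches 2000 m
    grid_cell_deg: float = 0.1
    grid_extent_km: float = 700.0
    n_fishing_events: int = 60  # several vessels, a few hauls/day each
    fledging_effects: FledgingEffects = field(default_factory=FledgingEffects)

    def __post_init__(self):
        if self.fix_interval_s <= 0:
            raise ValueError("fix_interval_s must be > 0")
        if not (0.0 <= self.icc_boldness < 1.0):
            raise ValueError("icc_boldness must be in [0, 1)")
        if min(self.commute_speed_kmh, self.forage_speed_kmh) <= 0:
            raise ValueError("speeds must be > 0")
        if self.patch_radius_km <= 0:
            raise ValueError("patch_radius_km must be > 0")

    def rng(self, *stream) -> np.random.Generator:
        """Deterministic substream keyed on (seed, *stream ints)."""
        return np.random.default_rng(
            np.random.SeedSequence(self.seed, spawn_key=tuple(int(s) for s in stream))
        )


@dataclass
class GroundTruth:
    """Planted quantities, recorded at generation time and then immutable."""

    patches: list = field(default_factory=list)  # per trip: dicts with centre/radius
    boldness_latent: dict = field(default_factory=dict)  # bird -> latent value
    icc_boldness: float | None = None
    fledging_effects: dict | None = None
    ssta_by_year: dict = field(default_factory=dict)
    sexes: dict = field(default_factory=dict)

    def to_json(self, path):
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=1, default=float)


# ---------------------------------------------------------------------------
# geometry helpers (local tangent plane at the colony)


def xy_to_latlon(x_km, y_km, colony):
    lat = colony[0] + np.asarray(y_km) / KM_PER_DEG_LAT
    lon = colony[1] + np.asarray(x_km) / (KM_PER_DEG_LAT * np.cos(np.radians(colony[0])))
    return lat, lon


def latlon_to_xy(lat, lon, colony):
    y = (np.asarray(lat) - colony[0]) * KM_PER_DEG_LAT
    x = (np.asarray(lon) - colony[1]) * KM_PER_DEG_LAT * np.cos(np.radians(colony[0]))
    return x, y


# ---------------------------------------------------------------------------
# bird-level latent structure


def bird_latent_boldness_z(config: SimConfig) -> np.ndarray:
    """Standardised latent boldness per bird, shared across generators so
    behaviour at the nest and foraging style are drawn from one
    individual axis."""
    return config.rng(7).standard_normal(config.n_birds)


def bird_foraging_preferences(config: SimConfig):
    """Per-bird preferred patch distance (km) and bearing (deg).

    The distance percentile mixes the (negated) boldness axis with an
    independent bird effect at ``syndrome_strength``, so bolder birds
    prefer patches nearer the colony; bearings are individual habits.
    """
    from scipy.stats import norm

    rng = config.rng(8)
    z = bird_latent_boldness_z(config)
    rho = config.syndrome_strength
    e = rng.standard_normal(config.n_birds)
    pct = norm.cdf(-rho * z + np.sqrt(max(0.0, 1 - rho**2)) * e)
    lo, hi = config.patch_distance_km
    pref_dist = lo + (hi - lo) * pct
    pref_bearing = rng.uniform(0, 360, config.n_birds)
    return pref_dist, pref_bearing


# ---------------------------------------------------------------------------
# GPS tracks


def simulate_track(config: SimConfig, bird_id: int, trip_index: int,
                   start_time: pd.Timestamp | None = None,
                   patch_bearings_deg=None, patch_distances_km=None):
    """One foraging trip as a two-state correlated random walk.

    Returns (fix DataFrame, ground-truth dict).  The walk commutes from the
    colony toward each planted patch with high directional persistence,
    switches to slow sinuous search inside the patch for ``patch_dwell_h``
    hours, then returns; fixes are emitted every ``fix_interval_s`` seconds
    and the trip starts and ends at the colony.
    """
    rng = config.rng(1, bird_id, trip_index)
    if start_time is None:
        start_time = pd.Timestamp("2011-12-20T06:00:00Z")
    dt_h = config.fix_interval_s / 3600.0
    # plant patch centres around this bird's preferred distance and bearing
    k = config.patch_count
    lo, hi = config.patch_distance_km
    if k and (patch_bearings_deg is None or patch_distances_km is None):
        pref_d, pref_b = bird_foraging_preferences(config)
        if patch_bearings_deg is None:
            patch_bearings_deg = np.mod(
                rng.normal(pref_b[bird_id], config.trip_bearing_sd_deg, size=k), 360.0
            )
        if patch_distances_km is None:
            patch_distances_km = np.clip(
                rng.normal(pref_d[bird_id], config.trip_distance_sd_km, size=k),
                0.8 * lo, 1.2 * hi,
            )
    bearings = np.radians(np.atleast_1d(patch_bearings_deg)) if k else np.empty(0)
    dists = np.atleast_1d(patch_distances_km) if k else np.empty(0)
    centres = np.column_stack([dists * np.sin(bearings), dists * np.cos(bearings)])
    waypoints = list(centres)
    is_patch = [True] * k
    if k == 0:
        # patch-free null trip: commute out to a turnaround point and back
        lo, hi = config.patch_distance_km
        brg = rng.uniform(0, 2 * np.pi)
        d = rng.uniform(lo, hi)
        waypoints.append(np.array([d * np.sin(brg), d * np.cos(brg)]))
        is_patch.append(False)
    waypoints.append(np.array([0.0, 0.0]))  # home
    is_patch.append(False)

    x = np.array([0.0, 0.0])
    heading = 0.0
    pts = [x.copy()]
    states = ["commute"]
    target_i = 0
    dwell_left = 0.0
    last = len(waypoints) - 1
    max_steps = int(200.0 / dt_h)  # hard cap: 200 h
    for _ in range(max_steps):
        tgt = waypoints[target_i]
        d_tgt = float(np.hypot(*(x - tgt)))
        if is_patch[target_i] and d_tgt <= config.patch_radius_km and dwell_left == 0.0:
            dwell_left = config.patch_dwell_h
        foraging = is_patch[target_i] and dwell_left > 0.0
        if foraging:
            speed = config.forage_speed_kmh
            kappa = config.turn_concentration_forage
            if d_tgt > config.patch_radius_km:
                # drifted out: steer back toward the patch centre
                mean_dir = np.arctan2(tgt[0] - x[0], tgt[1] - x[1])
            else:
                mean_dir = heading
            dwell_left = max(0.0, dwell_left - dt_h)
            if dwell_left == 0.0:
                target_i += 1
        else:
            if not is_patch[target_i] and target_i < last and d_tgt <= 5.0:
                target_i += 1
                tgt = waypoints[target_i]
            speed = config.commute_speed_kmh
            kappa = config.turn_concentration_commute
            mean_dir = np.arctan2(tgt[0] - x[0], tgt[1] - x[1])
        heading = rng.vonmises(mean_dir, kappa)
        x = x + speed * dt_h * np.array([np.sin(heading), np.cos(heading)])
        pts.append(x.copy())
        states.append("forage" if foraging else "commute")
        if target_i == last and np.hypot(*x) <= 1.0:
            break
    pts = np.asarray(pts)
    # close the trip at the colony
    pts = np.vstack([pts, [0.0, 0.0]])
    states.append("commute")
    lat, lon = xy_to_latlon(pts[:, 0], pts[:, 1], config.colony)
    times = start_time + pd.to_timedelta(
        np.arange(len(pts)) * config.fix_interval_s, unit="s"
    )
    fixes = pd.DataFrame(
        {
            "bird_id": f"bird{bird_id:03d}",
            "trip_id": f"bird{bird_id:03d}_trip{trip_index}",
            "timestamp": times,
            "lat": lat,
            "lon": lon,
            "state": states,
        }
    )
    clat, clon = xy_to_latlon(centres[:, 0], centres[:, 1], config.colony)
    truth = {
        "bird_id": f"bird{bird_id:03d}",
        "trip_index": trip_index,
        "patch_centres_latlon": np.column_stack([np.atleast_1d(clat), np.atleast_1d(clon)]).tolist(),
        "patch_radius_km": config.patch_radius_km,
    }
    return fixes, truth


def simulate_gps(config: SimConfig, phase: str = "brooding"):
    """All birds x trips, concatenated with at-colony fixes between trips so
    trip segmentation sees complete colony-to-colony excursions."""
    frames = []
    truths = []
    for b in range(config.n_birds):
        t0 = pd.Timestamp("2011-12-20T06:00:00Z")
        bird_frames = []
        for tr in range(config.trips_per_bird):
            fixes, truth = simulate_track(config, b, tr, start_time=t0)
            truths.append(truth)
            rest = fixes.iloc[[-1]].copy()  # sit at the nest between trips
            rest["timestamp"] = fixes["timestamp"].iloc[-1] + pd.Timedelta(hours=6)
            bird_frames.extend([fixes, rest])
            t0 = rest["timestamp"].iloc[0] + pd.Timedelta(seconds=config.fix_interval_s)
        df = pd.concat(bird_frames, ignore_index=True)
        df["phase"] = phase
        frames.append(df)
    return pd.concat(frames, ignore_index=True), truths


# ---------------------------------------------------------------------------
# bathymetry


def simulate_bathymetry(config: SimConfig):
    """Radially symmetric shelf profile around the colony.

    Depth rises from ~50 m at the colony to 200 m at ``shelf_km``, 2000 m at
    ``shelf_break_km``, and deepens by 5 m/km beyond, so all three habitat
    classes exist and depth is monotone along any radial transect.
    """
    from .spatial import BathymetryGrid

    half_deg_lat = config.grid_extent_km / KM_PER_DEG_LAT
    half_deg_lon = config.grid_extent_km / (
        KM_PER_DEG_LAT * np.cos(np.radians(config.colony[0]))
    )
    cell = config.grid_cell_deg
    nrows = int(np.ceil(2 * half_deg_lat / cell))
    ncols = int(np.ceil(2 * half_deg_lon / cell))
    yll = config.colony[0] - half_deg_lat
    xll = config.colony[1] - half_deg_lon
    lat_c = yll + (np.arange(nrows) + 0.5) * cell  # bottom-up
    lon_c = xll + (np.arange(ncols) + 0.5) * cell
    LON, LAT = np.meshgrid(lon_c, lat_c)
    x, y = latlon_to_xy(LAT, LON, config.colony)
    d = np.hypot(x, y)
    depth = np.where(
        d < config.shelf_km,
        50.0 + 149.0 * d / config.shelf_km,
        np.where(
            d < config.shelf_break_km,
            200.0 + 1800.0 * (d - config.shelf_km) / (config.shelf_break_km - config.shelf_km),
            2000.0 + 5.0 * (d - config.shelf_break_km),
        ),
    )
    depth = depth[::-1]  # store north-first, ESRI order
    return BathymetryGrid(xllcorner=xll, yllcorner=yll, cellsize=cell, depth=depth)


def depth_profile_km(config: SimConfig, d_km):
    """Closed-form radial depth used by the grid (for oracle checks)."""
    d = np.asarray(d_km, float)
    return np.where(
        d < config.shelf_km,
        50.0 + 149.0 * d / config.shelf_km,
        np.where(
            d < config.shelf_break_km,
            200.0 + 1800.0 * (d - config.shelf_km) / (config.shelf_break_km - config.shelf_km),
            2000.0 + 5.0 * (d - config.shelf_break_km),
        ),
    )


# ---------------------------------------------------------------------------
# fishing events


def simulate_fishing_events(config: SimConfig,
                            window=("2011-12-20", "2011-12-24")) -> pd.DataFrame:
    """Longline set/haul records with haul-end points on the shelf edge.

    Lines are set at night and hauled hours later; the haul-end point (the
    start of discarding) falls in the 200-2000 m depth band by placing it
    between ``shelf_km`` and ``shelf_break_km`` from the colony.
    """
    rng = config.rng(2)
    n = config.n_fishing_events
    t0, t1 = (pd.Timestamp(w) for w in window)
    t0 = t0.tz_localize("UTC") if t0.tzinfo is None else t0
    t1 = t1.tz_localize("UTC") if t1.tzinfo is None else t1
    span_h = (t1 - t0).total_seconds() / 3600.0
    rows = []
    for i in range(n):
        # keep away from the exact band edges so grid discretisation cannot
        # push a haul point out of the shelf-edge depth class
        d = rng.uniform(config.shelf_km * 1.1, config.shelf_break_km * 0.9)
        brg = rng.uniform(0, 2 * np.pi)
        hx, hy = d * np.sin(brg), d * np.cos(brg)
        # setting position a short steam away
        sx = hx + rng.normal(0, 3.0)
        sy = hy + rng.normal(0, 3.0)
        haul_end = t0 + pd.Timedelta(hours=float(rng.uniform(12.0, span_h - 1.0)))
        haul_start = haul_end - pd.Timedelta(hours=float(rng.uniform(2.0, 5.0)))
        set_end = haul_start - pd.Timedelta(hours=float(rng.uniform(4.0, 8.0)))
        set_start = set_end - pd.Timedelta(hours=float(rng.uniform(2.0, 4.0)))
        hlat, hlon = xy_to_latlon(hx, hy, config.colony)
        slat, slon = xy_to_latlon(sx, sy, config.colony)
        rows.append(
            {
                "line_id": f"line{i:03d}",
                "set_start": set_start, "set_end": set_end,
                "haul_start": haul_start, "haul_end": haul_end,
                "set_lat": float(slat), "set_lon": float(slon),
                "haul_lat": float(hlat), "haul_lon": float(hlon),
            }
        )
    cols = ["line_id", "set_start", "set_end", "haul_start", "haul_end",
            "set_lat", "set_lon", "haul_lat", "haul_lon"]
    return pd.DataFrame(rows, columns=cols)


# ---------------------------------------------------------------------------
# novel-object behaviour


# per-variable (intercept, loading on the latent axis) for the Poisson
# log-rates; snapping and sitting load against the latent boldness axis
BEHAVIOUR_LOADINGS = {
    "peck_count": (1.2, 0.9),
    "lunge_count": (0.8, 0.8),
    "vocalise_count": (1.0, 0.7),
    "snap_count": (0.7, -0.5),
}


def simulate_behaviour(config: SimConfig, noise_sd: float = 1.0) -> tuple[pd.DataFrame, dict]:
    """Novel-object test counts with a latent per-bird boldness value.

    The latent observation value is bird + noise with
    var(bird)/var(total) = ``icc_boldness``; counts are Poisson with
    log-rate linear in the latent value (log-normal bird effect over
    Poisson counts) and sitting seconds are a bounded logistic transform.
    A ``retest_fraction`` of birds is observed twice, >= 7 days apart.
    """
    rng = config.rng(3)
    icc = config.icc_boldness
    if icc > 0 and noise_sd > 0:
        sd_bird = noise_sd * np.sqrt(icc / (1.0 - icc))
    elif noise_sd == 0:
        sd_bird = 1.0
    else:
        sd_bird = 0.0
    latent_bird = sd_bird * bird_latent_boldness_z(config)  # shared bird axis
    n_retest = int(round(config.retest_fraction * config.n_birds))
    retested = rng.choice(config.n_birds, size=n_retest, replace=False)
    rows, latent_obs = [], []
    season_start = pd.Timestamp("2011-12-20")
    for b in range(config.n_birds):
        n_obs = 2 if b in retested else 1
        day0 = int(rng.integers(0, 20))
        for o in range(n_obs):
            lat_obs = latent_bird[b] + rng.normal(0.0, noise_sd)
            latent_obs.append(float(lat_obs))
            row = {
                "bird_id": f"bird{b:03d}",
                "obs_number": o + 1,
                "date": season_start + pd.Timedelta(days=day0 + o * int(rng.integers(7, 14))),
            }
            for var, (a, c) in BEHAVIOUR_LOADINGS.items():
                row[var] = int(rng.poisson(np.exp(a + c * lat_obs)))
            # seconds sitting in the scored 30 s window, bolder birds stand
            row["sitting_s"] = float(np.round(30.0 / (1.0 + np.exp(0.8 * lat_obs)), 1))
            rows.append(row)
    truth = {
        "bird": {f"bird{b:03d}": float(latent_bird[b]) for b in range(config.n_birds)},
        "obs": latent_obs,  # row-aligned; ICC of this column is the planted value
    }
    return pd.DataFrame(rows), truth


# ---------------------------------------------------------------------------
# breeding histories and SSTa


def simulate_ssta(config: SimConfig) -> pd.DataFrame:
    """Yearly Sep-Nov SSTa: bands balanced over the study period, values
    uniform within each tercile range."""
    rng = config.rng(4)
    bands = np.array((["low", "medium", "high"] * config.years)[: config.years])
    rng.shuffle(bands)
    vals = np.array([rng.uniform(*SSTA_BANDS[b]) for b in bands])
    years = np.arange(2011 - config.years + 1, 2011 + 1)
    return pd.DataFrame({"year": years, "ssta": vals, "band": bands})


def simulate_sexes(config: SimConfig) -> dict[str, str]:
    rng = config.rng(5)
    male = rng.random(config.n_birds) < config.sex_ratio
    return {f"bird{b:03d}": ("male" if m else "female") for b, m in enumerate(male)}


def simulate_breeding(config: SimConfig, scores: pd.Series,
                      sexes: dict[str, str] | None = None,
                      ssta: pd.DataFrame | None = None):
    """Bernoulli fledging outcomes per bird-year under the planted
    log-odds model; returns (breeding table, ssta table, truth dict)."""
    rng = config.rng(6)
    if sexes is None:
        sexes = simulate_sexes(config)
    if ssta is None:
        ssta = simulate_ssta(config)
    e = config.fledging_effects
    rows = []
    for bird, s in scores.items():
        m = 1.0 if sexes[bird] == "male" else 0.0
        for _, yr in ssta.iterrows():
            a = yr["ssta"]
            eta = (e.intercept + e.score * s + e.sex * m + e.ssta * a
                   + e.score_sex * s * m + e.score_ssta * s * a
                   + e.sex_ssta * m * a + e.score_sex_ssta * s * m * a)
            rows.append(
                {
                    "bird_id": bird,
                    "year": int(yr["year"]),
                    "sex": sexes[bird],
                    "success": int(rng.random() < 1.0 / (1.0 + np.exp(-eta))),
                }
            )
    truth = {"fledging_effects": asdict(e),
             "ssta_by_year": dict(zip(ssta["year"].astype(int), ssta["ssta"]))}
    return pd.DataFrame(rows), ssta, truth


# ---------------------------------------------------------------------------
# full-dataset convenience + writers


def write_gps_csv(df: pd.DataFrame, path):
    out = df.copy()
    out["timestamp"] = out["timestamp"].dt.strftime("%Y-%m-%dT%H:%M:%SZ")
    cols = ["bird_id", "trip_id", "timestamp", "lat", "lon"]
    extra = [c for c in ("phase",) if c in out.columns]
    out[cols + extra].to_csv(path, index=False)


def write_fishing_csv(df: pd.DataFrame, path):
    out = df.copy()
    for c in ("set_start", "set_end", "haul_start", "haul_end"):
        out[c] = out[c].dt.strftime("%Y-%m-%dT%H:%M:%SZ")
    out.to_csv(path, index=False)
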