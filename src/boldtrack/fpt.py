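"""First-passage-time (FPT) analysis and area-restricted-search detection.

FPT at a track point for radius *r* is the time the animal spends inside the
circle of radius *r* centred on that point: the first exit searching forward
in time minus the first exit searching backward (Fauchald & Tveraa
convention).  The variance of log FPT across points peaks at the spatial
scale of intensive search; contiguous stretches with FPT above a threshold
at that scale, merged when their centres fall within a minimum separation,
are the ARS (foraging) zones.

Tracks are first speed-filtered and re-sampled every ``step_km`` (1 km by
default) of along-path distance so that FPT is evaluated on an even spatial
grid, as is standard for this method.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .tracks import Trip, haversine_km

logger = logging.getLogger(__name__)


@dataclass
class InterpolatedPath:
    """Track re-sampled every ``step_km`` of cumulative along-path distance."""

    lat: np.ndarray
    lon: np.ndarray
    t_s: np.ndarray  # seconds since first point
    cumdist_km: np.ndarray
    step_km: float
    trip_id: str | None = None

    def __len__(self):
        return len(self.lat)


@dataclass
class FPTProfile:
    """FPT (hours) at every path point for every radius; NaN = circle never
    fully crossed in one of the two directions."""

    radii_km: np.ndarray
    fpt_h: np.ndarray  # shape (n_points, n_radii)
    trip_id: str | None = None


@dataclass(frozen=True)
class VariancePeak:
    radius_km: float
    variance: float  # var of log FPT at the peak radius
    threshold_h: float | None = None  # FPT threshold at this radius


@dataclass
class ARSZone:
    member_idx: np.ndarray  # path point indices (sorted, may span merged runs)
    centre: tuple[float, float]  # (lat, lon), arithmetic mean of members
    mean_fpt_h: float
    trip_id: str | None = None


def interpolate_path(trip: Trip, step_km: float = 1.0) -> InterpolatedPath | None:
    """Linear re-sampling of a filtered trip every ``step_km`` along-path km.

    Positions and times are interpolated linearly between bracketing fixes.
    Returns None (with a warning) for paths shorter than two steps.
    """
    df = trip.fixes
    lat = df["lat"].to_numpy(float)
    lon = df["lon"].to_numpy(float)
    t = df["timestamp"]
    t_s = (t - t.iloc[0]).dt.total_seconds().to_numpy()
    seg = haversine_km((lat[:-1], lon[:-1]), (lat[1:], lon[1:]))
    # collapse zero-length segments so cumulative distance is strictly increasing
    keep = np.concatenate([[True], seg > 1e-9])
    lat, lon, t_s = lat[keep], lon[keep], t_s[keep]
    if len(lat) < 2:
        logger.warning("trip %s: degenerate path, skipped", trip.trip_id)
        return None
    seg = haversine_km((lat[:-1], lon[:-1]), (lat[1:], lon[1:]))
    cum = np.concatenate([[0.0], np.cumsum(seg)])
    if cum[-1] < 2 * step_km:
        logger.warning(
            "trip %s: path length %.2f km < 2 steps, skipped", trip.trip_id, cum[-1]
        )
        return None
    grid = np.arange(0.0, cum[-1] + 1e-6, step_km)  # 1 mm slack at the end
    return InterpolatedPath(
        lat=np.interp(grid, cum, lat),
        lon=np.interp(grid, cum, lon),
        t_s=np.interp(grid, cum, t_s),
        cumdist_km=grid,
        step_km=step_km,
        trip_id=trip.trip_id,
    )


def _directional_exit_times(lat: np.ndarray, lon: np.ndarray, d: np.ndarray,
                            t: np.ndarray, radii: np.ndarray,
                            centre: tuple[float, float]) -> np.ndarray:
    """First exit time for each radius along one direction.

    ``lat, lon`` are successive path points (point 0 is the circle
    centre), ``d`` their great-circle distances from ``centre``, ``t`` the
    matching times.  The first exit for radius r is the first index where
    the running maximum of ``d`` exceeds r; the exit time is then refined
    by bisecting the great-circle distance along the linearly-interpolated
    crossing segment (distance along a segment is convex, and d[j-1] <= r
    < d[j], so the root is unique).  NaN where the path never exits.
    """
    out = np.full(len(radii), np.nan)
    if len(d) < 2:
        return out
    runmax = np.maximum.accumulate(d)
    # first index j with runmax[j] > r  (runmax is sorted, so searchsorted works)
    j = np.searchsorted(runmax, radii, side="right")
    ok = j < len(d)
    if not ok.any():
        return out
    jj = j[ok]
    r = radii[ok]
    lat0, lon0 = lat[jj - 1], lon[jj - 1]
    dlat, dlon = lat[jj] - lat0, lon[jj] - lon0
    lo = np.zeros(len(jj))
    hi = np.ones(len(jj))
    for _ in range(30):  # ~1e-9 of a segment
        mid = 0.5 * (lo + hi)
        dm = haversine_km((lat0 + mid * dlat, lon0 + mid * dlon), centre)
        above = dm > r
        hi = np.where(above, mid, hi)
        lo = np.where(above, lo, mid)
    s = 0.5 * (lo + hi)
    out[ok] = t[jj - 1] + s * (t[jj] - t[jj - 1])
    return out


def first_passage_time(path: InterpolatedPath, i: int, radius_km: float) -> float:
    """FPT (hours) for the circle of ``radius_km`` centred at path point i.

    NaN when the path never exits the circle forward or backward in time.
    """
    return float(
        fpt_profile(path, np.asarray([radius_km], float), points=[i]).fpt_h[0, 0]
    )


def fpt_profile(
    path: InterpolatedPath,
    radii_km=None,
    points=None,
) -> FPTProfile:
    """FPT at every path point (or a subset) for every radius in the sweep.

    Default sweep: 1..100 km in 1 km steps.
    """
    if radii_km is None:
        radii_km = np.arange(1.0, 101.0)
    radii = np.asarray(radii_km, float)
    idx = np.arange(len(path)) if points is None else np.asarray(points, int)
    fpt = np.full((len(idx), len(radii)), np.nan)
    lat, lon, t = path.lat, path.lon, path.t_s
    for row, i in enumerate(idx):
        centre = (lat[i], lon[i])
        d = haversine_km(centre, (lat, lon))
        fwd = _directional_exit_times(lat[i:], lon[i:], d[i:], t[i:], radii, centre)
        # backward search: reverse the path, negate time so it increases
        bwd = _directional_exit_times(lat[i::-1], lon[i::-1], d[i::-1],
                                      -t[i::-1], radii, centre)
        fpt[row] = (fwd + bwd) / 3600.0  # t_exit_fwd - t_exit_bwd
    return FPTProfile(radii_km=radii, fpt_h=fpt, trip_id=path.trip_id)


def variance_curve(profile: FPTProfile, min_points: int = 5) -> np.ndarray:
    """Sample variance of log FPT per radius; NaN where < ``min_points``
    points have a defined FPT."""
    out = np.full(len(profile.radii_km), np.nan)
    for k in range(profile.fpt_h.shape[1]):
        col = profile.fpt_h[:, k]
        vals = col[np.isfinite(col) & (col > 0)]
        if len(vals) >= min_points:
            out[k] = np.var(np.log(vals), ddof=1)
    return out


def detect_peaks(
    radii_km: np.ndarray,
    variance: np.ndarray,
    prominence_frac: float = 0.10,
    max_peaks: int = 2,
    min_variance: float = 0.05,
) -> list[VariancePeak]:
    """Local maxima of the log-FPT variance curve.

    A peak must strictly exceed both defined neighbours and reach at least
    ``prominence_frac`` of the curve maximum.  Ties break toward the smaller
    radius; at most ``max_peaks`` peaks are kept, by descending variance.

    ``min_variance`` is an absolute floor on the whole curve: a track whose
    log-FPT variance never reaches it (e.g. pure commuting at near-constant
    speed, where FPT is essentially 2r/v everywhere) carries no
    multi-scale signal and yields no peaks.
    """
    s = np.asarray(variance, float)
    defined = np.flatnonzero(np.isfinite(s))
    if len(defined) < 3:
        return []
    vmax = np.nanmax(s)
    if not np.isfinite(vmax) or vmax <= 0 or vmax < min_variance:
        return []
    cand: list[VariancePeak] = []
    vals = s[defined]
    for pos in range(1, len(defined)):
        if vals[pos] <= vals[pos - 1]:
            continue  # not a strict rise onto this point
        # find the next strictly different value to the right (plateau-aware);
        # the leftmost plateau point carries the peak (tie toward small radius)
        nxt = pos + 1
        while nxt < len(defined) and vals[nxt] == vals[pos]:
            nxt += 1
        if nxt >= len(defined) or vals[nxt] >= vals[pos]:
            continue  # plateau runs off the end or rises again: no peak here
        if vals[pos] >= prominence_frac * vmax:
            i = defined[pos]
            cand.append(VariancePeak(radius_km=float(radii_km[i]), variance=float(s[i])))
    cand.sort(key=lambda p: (-p.variance, p.radius_km))
    return cand[:max_peaks]


def fpt_threshold(fpt_values_h: np.ndarray, min_values: int = 10) -> float | None:
    """Otsu split on log FPT, returned on the FPT (hours) scale.

    The threshold maximises the between-class variance of the two-group
    split of log FPT; exhaustive over the sorted sample, so it matches a
    brute-force search exactly.  None when fewer than ``min_values`` defined
    values are available (zone extraction is then skipped for the trip).
    """
    v = np.asarray(fpt_values_h, float)
    v = v[np.isfinite(v) & (v > 0)]
    if len(v) < min_values:
        return None
    x = np.sort(np.log(v))
    n = len(x)
    csum = np.cumsum(x)
    total = csum[-1]
    k = np.arange(1, n)  # split: x[:k] | x[k:]
    mu1 = csum[:-1] / k
    mu2 = (total - csum[:-1]) / (n - k)
    between = k * (n - k) * (mu1 - mu2) ** 2  # / n^2, monotone-irrelevant
    valid = x[k - 1] < x[k]  # split must separate distinct values
    if not valid.any():
        return None
    between = np.where(valid, between, -np.inf)
    kbest = k[int(np.argmax(between))]
    cut = 0.5 * (x[kbest - 1] + x[kbest])
    return float(np.exp(cut))


def extract_ars_zones(
    path: InterpolatedPath,
    profile: FPTProfile,
    peak: VariancePeak,
    min_sep_km: float = 10.0,
) -> list[ARSZone]:
    """Contiguous above-threshold runs at the peak radius, merged while any
    two zone centres are within ``min_sep_km`` of each other."""
    if peak.threshold_h is None:
        raise ValueError("peak has no FPT threshold; run fpt_threshold first")
    k = int(np.argmin(np.abs(profile.radii_km - peak.radius_km)))
    col = profile.fpt_h[:, k]
    above = np.isfinite(col) & (col > peak.threshold_h)
    padded = np.concatenate([[False], above, [False]])
    starts = np.flatnonzero(~padded[:-1] & padded[1:])
    ends = np.flatnonzero(padded[:-1] & ~padded[1:])
    zones = [_make_zone(path, col, np.arange(s, e)) for s, e in zip(starts, ends)]
    # merge-until-stable on centre-to-centre separation
    merged = True
    while merged and len(zones) > 1:
        merged = False
        for a in range(len(zones)):
            for b in range(a + 1, len(zones)):
                if haversine_km(zones[a].centre, zones[b].centre) <= min_sep_km:
                    members = np.union1d(zones[a].member_idx, zones[b].member_idx)
                    newzone = _make_zone(path, col, members)
                    zones = [z for j, z in enumerate(zones) if j not in (a, b)]
                    zones.append(newzone)
                    merged = True
                    break
            if merged:
                break
    zones.sort(key=lambda z: z.member_idx[0])
    return zones


def _make_zone(path: InterpolatedPath, fpt_col: np.ndarray, members: np.ndarray) -> ARSZone:
    return ARSZone(
        member_idx=members,
        centre=(float(path.lat[members].mean()), float(path.lon[members].mean())),
        mean_fpt_h=float(np.nanmean(fpt_col[members])),
        trip_id=path.trip_id,
    )


def analyse_trip(
    trip: Trip,
    step_km: float = 1.0,
    radii_km=None,
    min_sep_km: float = 10.0,
    prominence_frac: float = 0.10,
    max_peaks: int = 2,
):
    """Full FPT/ARS pipeline for one speed-filtered trip.

    Returns (path, profile, peak, zones); any element from the first
    unavailable stage onward is None/[] (short path, no variance peak, or
    too few defined FPT values for a threshold).  The largest-variance peak
    is the one used for zone extraction.
    """
    path = interpolate_path(trip, step_km=step_km)
    if path is None:
        return None, None, None, []
    profile = fpt_profile(path, radii_km=radii_km)
    var = variance_curve(profile)
    peaks = detect_peaks(profile.radii_km, var, prominence_frac, max_peaks)
    if not peaks:
        return path, profile, None, []
    peak = peaks[0]
    k = int(np.argmin(np.abs(profile.radii_km - peak.radius_km)))
    thr = fpt_threshold(profile.fpt_h[:, k])
    if thr is None:
        return path, profile, peak, []
    peak = VariancePeak(radius_km=peak.radius_km, variance=peak.variance, threshold_h=thr)
    zones = extract_ars_zones(path, profile, peak, min_sep_km=min_sep_km)
    return path, profile, peak, zones
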