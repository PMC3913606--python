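"""Shared fixtures: small synthetic datasets built at test time."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from boldtrack import synthetic, tracks

COLONY = (-48.4, 68.4)


def make_trip(xy_km, colony=COLONY, dt_s=120.0, bird_id="b1", trip_id="b1_t1"):
    """Build a Trip from local east/north offsets (km) with fixed time step."""
    xy = np.asarray(xy_km, float)
    lat, lon = synthetic.xy_to_latlon(xy[:, 0], xy[:, 1], colony)
    t = pd.date_range("2011-12-20T06:00:00Z", periods=len(xy), freq=f"{int(dt_s)}s")
    df = pd.DataFrame({"timestamp": t, "lat": lat, "lon": lon})
    return tracks.Trip(trip_id=trip_id, bird_id=bird_id, fixes=df, complete=True)


def straight_trip(length_km=40.0, speed_kmh=30.0, bearing_deg=90.0, dt_s=120.0):
    """Constant-speed straight-line trip of given length."""
    step = speed_kmh * dt_s / 3600.0
    n = int(length_km / step) + 1
    d = np.arange(n) * step
    b = np.radians(bearing_deg)
    xy = np.column_stack([d * np.sin(b), d * np.cos(b)])
    return make_trip(xy, dt_s=dt_s)


@pytest.fixture(scope="session")
def colony():
    return COLONY


@pytest.fixture(scope="session")
def sim_config():
    return synthetic.SimConfig(seed=42, n_birds=4, trips_per_bird=2)


@pytest.fixture(scope="session")
def patch_trip(sim_config):
    """One simulated trip with a single planted patch, plus its truth."""
    fixes, truth = synthetic.simulate_track(
        sim_config, bird_id=0, trip_index=0,
        patch_bearings_deg=[90.0], patch_distances_km=[150.0],
    )
    trip = tracks.Trip(trip_id="sim0", bird_id="bird000", fixes=fixes, complete=True)
    return trip, truth
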