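"""The synthetic colony: determinism, planted-signal verifiability and the
physical plausibility of every generated input."""

import dataclasses

import numpy as np
import pandas as pd
import pytest
from scipy.special import expit

from boldtrack import models, spatial, synthetic, tracks
from boldtrack.synthetic import FledgingEffects, SimConfig


class TestConfigValidation:
    @pytest.mark.parametrize("kwargs", [
        {"fix_interval_s": 0},
        {"fix_interval_s": -10},
        {"icc_boldness": 1.0},
        {"icc_boldness": -0.1},
        {"commute_speed_kmh": 0.0},
        {"forage_speed_kmh": -1.0},
        {"patch_radius_km": 0.0},
    ])
    def test_invalid_parameters_rejected(self, kwargs):
        with pytest.raises(ValueError):
            SimConfig(seed=0, **kwargs)


class TestDeterminism:
    def test_same_seed_identical_tracks(self):
        cfg = SimConfig(seed=5, n_birds=2, trips_per_bird=1)
        a, _ = synthetic.simulate_gps(cfg)
        b, _ = synthetic.simulate_gps(cfg)
        pd.testing.assert_frame_equal(a, b)

    def test_same_seed_identical_everything_else(self):
        cfg = SimConfig(seed=6, n_birds=5)
        for fn in (synthetic.simulate_fishing_events, synthetic.simulate_ssta):
            pd.testing.assert_frame_equal(fn(cfg), fn(cfg))
        b1, t1 = synthetic.simulate_behaviour(cfg)
        b2, t2 = synthetic.simulate_behaviour(cfg)
        pd.testing.assert_frame_equal(b1, b2)
        assert t1 == t2

    def test_different_seeds_differ(self):
        a, _ = synthetic.simulate_gps(SimConfig(seed=1, n_birds=1, trips_per_bird=1))
        b, _ = synthetic.simulate_gps(SimConfig(seed=2, n_birds=1, trips_per_bird=1))
        assert not a[["lat", "lon"]].equals(b[["lat", "lon"]])


class TestTrackStructure:
    def test_trip_starts_and_ends_at_colony(self, sim_config):
        fixes, _ = synthetic.simulate_track(sim_config, 0, 0)
        d0 = tracks.haversine_km((fixes["lat"].iloc[0], fixes["lon"].iloc[0]),
                                 sim_config.colony)
        d1 = tracks.haversine_km((fixes["lat"].iloc[-1], fixes["lon"].iloc[-1]),
                                 sim_config.colony)
        assert d0 < 2.0 and d1 < 2.0

    def test_fix_cadence_matches_interval(self, sim_config):
        fixes, _ = synthetic.simulate_track(sim_config, 0, 0)
        dt = fixes["timestamp"].diff().dt.total_seconds().iloc[1:]
        assert (dt == sim_config.fix_interval_s).all()

    def test_patch_dwell_fraction(self, sim_config):
        """A 5 km patch planted at 150 km holds >= 30% of fix time."""
        fixes, truth = synthetic.simulate_track(
            sim_config, 0, 0, patch_bearings_deg=[90.0], patch_distances_km=[150.0])
        centre = tuple(truth["patch_centres_latlon"][0])
        d = tracks.haversine_km((fixes["lat"].to_numpy(), fixes["lon"].to_numpy()), centre)
        assert (d <= truth["patch_radius_km"]).mean() >= 0.30

    def test_fixes_belong_to_one_bird_and_trip(self):
        cfg = SimConfig(seed=9, n_birds=3, trips_per_bird=2)
        gps, _ = synthetic.simulate_gps(cfg)
        per_fix = gps.groupby(["bird_id", "timestamp"]).size()
        assert (per_fix == 1).all()
        assert (gps.groupby("trip_id")["bird_id"].nunique() == 1).all()

    def test_commute_speed_is_as_configured(self, sim_config):
        fixes, _ = synthetic.simulate_track(sim_config, 1, 0)
        trip = tracks.compute_speeds(
            tracks.Trip("t", "b", fixes, complete=True))
        commute = trip.fixes[np.asarray(fixes["state"] == "commute")]
        med = commute["speed_kmh"].iloc[5:-5].median()
        assert med == pytest.approx(sim_config.commute_speed_kmh, rel=0.05)


class TestBathymetry:
    def test_colony_on_shelf_and_deep_beyond_break(self):
        cfg = SimConfig(seed=1, n_birds=2)
        grid = synthetic.simulate_bathymetry(cfg)
        assert grid.depth_at(*cfg.colony) < 200
        lat, lon = synthetic.xy_to_latlon(350.0, 0.0, cfg.colony)
        assert grid.depth_at(float(lat), float(lon)) > 2000

    def test_monotone_along_radial_transect(self):
        cfg = SimConfig(seed=1, n_birds=2)
        grid = synthetic.simulate_bathymetry(cfg)
        r = np.linspace(5, 600, 120)
        lat, lon = synthetic.xy_to_latlon(r * np.sin(0.7), r * np.cos(0.7), cfg.colony)
        depths = np.array([grid.depth_at(float(a), float(o)) for a, o in zip(lat, lon)])
        assert (np.diff(depths) >= -1e-9).all()

    def test_all_three_habitat_classes_present(self):
        grid = synthetic.simulate_bathymetry(SimConfig(seed=1, n_birds=2))
        classes = {spatial.classify_habitat(d) for d in grid.depth.ravel()}
        assert classes == {"shelf", "shelf_edge", "oceanic"}


class TestFishingEvents:
    def test_zero_events(self):
        cfg = SimConfig(seed=2, n_birds=2, n_fishing_events=0)
        df = synthetic.simulate_fishing_events(cfg)
        assert len(df) == 0
        zones = spatial.build_discarding_zones(df)
        assert not spatial.fix_overlap(-48.0, 69.0,
                                       pd.Timestamp("2011-12-21T12:00Z"), zones)

    def test_haul_end_points_on_shelf_edge(self):
        cfg = SimConfig(seed=3, n_birds=2, n_fishing_events=40)
        grid = synthetic.simulate_bathymetry(cfg)
        df = synthetic.simulate_fishing_events(cfg)
        depths = np.array([grid.depth_at(la, lo)
                           for la, lo in zip(df["haul_lat"], df["haul_lon"])])
        assert ((depths >= 200) & (depths <= 2000)).all()

    def test_event_time_ordering(self):
        df = synthetic.simulate_fishing_events(SimConfig(seed=4, n_birds=2))
        assert ((df["set_start"] < df["set_end"])
                & (df["set_end"] <= df["haul_start"])
                & (df["haul_start"] < df["haul_end"])).all()

    def test_planted_haul_at_fix_overlaps(self):
        """A discarding zone centred on a known fix position and time must
        capture that fix."""
        t = pd.Timestamp("2011-12-21T10:00:00Z")
        df = pd.DataFrame([{
            "line_id": "l0",
            "set_start": t - pd.Timedelta(hours=12),
            "set_end": t - pd.Timedelta(hours=10),
            "haul_start": t - pd.Timedelta(hours=2), "haul_end": t,
            "set_lat": -48.0, "set_lon": 69.0, "haul_lat": -48.2, "haul_lon": 69.1,
        }])
        zones = spatial.build_discarding_zones(df)
        assert spatial.fix_overlap(-48.2, 69.1, t + pd.Timedelta(minutes=30), zones)


class TestBehaviour:
    def test_latent_icc_zero_estimates_near_zero(self):
        cfg = SimConfig(seed=10, n_birds=500, icc_boldness=0.0, retest_fraction=1.0)
        beh, truth = synthetic.simulate_behaviour(cfg)
        fit = models.fit_lmm_random_intercept(
            np.asarray(truth["obs"]), np.ones((len(beh), 1)), beh["bird_id"])
        assert abs(models.repeatability(fit, n_boot=0).r) < 0.05

    def test_latent_icc_high_recovered(self):
        cfg = SimConfig(seed=11, n_birds=500, icc_boldness=0.9, retest_fraction=1.0)
        beh, truth = synthetic.simulate_behaviour(cfg)
        fit = models.fit_lmm_random_intercept(
            np.asarray(truth["obs"]), np.ones((len(beh), 1)), beh["bird_id"])
        assert models.repeatability(fit, n_boot=0).r == pytest.approx(0.9, abs=0.05)

    def test_zero_noise_gives_identical_counts_per_bird(self):
        cfg = SimConfig(seed=12, n_birds=30, icc_boldness=0.5, retest_fraction=1.0)
        beh, _ = synthetic.simulate_behaviour(cfg, noise_sd=0.0)
        # zero observation noise: the latent value is fixed per bird, so
        # expected counts are equal across a bird's observations
        sit = beh.groupby("bird_id")["sitting_s"].nunique()
        assert (sit == 1).all()

    def test_retest_fraction(self):
        cfg = SimConfig(seed=13, n_birds=154, retest_fraction=16 / 154)
        beh, _ = synthetic.simulate_behaviour(cfg)
        assert (beh.groupby("bird_id").size() == 2).sum() == 16

    def test_count_channel_attenuates_but_preserves_ordering(self):
        """PC1 of the Poisson counts is a noisier readout of the same axis:
        estimated repeatability drops below the latent value but bird
        ordering is preserved (positive correlation with the latent)."""
        from boldtrack import personality
        cfg = SimConfig(seed=14, n_birds=300, icc_boldness=0.9, retest_fraction=1.0)
        beh, truth = synthetic.simulate_behaviour(cfg)
        pca = personality.pca_correlation(beh, personality.BOLDNESS_VARS,
                                          sign_anchor="peck_count")
        pc1 = personality.project_pc1(pca, beh)
        fit = models.fit_lmm_random_intercept(pc1, np.ones((len(beh), 1)),
                                              beh["bird_id"])
        r_pc1 = models.repeatability(fit, n_boot=0).r
        assert 0.3 < r_pc1 < 0.9
        r_axis = np.corrcoef(pc1, truth["obs"])[0, 1]
        assert r_axis > 0.5


class TestBreeding:
    def test_ssta_within_tercile_ranges(self):
        ssta = synthetic.simulate_ssta(SimConfig(seed=20, n_birds=5))
        assert len(ssta) == 23
        assert ssta["ssta"].between(-0.60, 0.13).all()
        for band, (lo, hi) in synthetic.SSTA_BANDS.items():
            vals = ssta.loc[ssta["band"] == band, "ssta"]
            assert vals.between(lo, hi).all()

    def test_null_effects_fledging_rate_is_expit_intercept(self):
        cfg = SimConfig(seed=21, n_birds=300, years=23,
                        fledging_effects=FledgingEffects(
                            intercept=0.3, ssta=0.0))
        idx = [f"bird{b:03d}" for b in range(cfg.n_birds)]
        scores = pd.Series(np.zeros(cfg.n_birds), index=idx)
        breeding, _, _ = synthetic.simulate_breeding(cfg, scores)
        assert breeding["success"].mean() == pytest.approx(expit(0.3), abs=0.02)

    def test_seeded_reproducibility(self):
        cfg = SimConfig(seed=22, n_birds=20)
        idx = [f"bird{b:03d}" for b in range(cfg.n_birds)]
        scores = pd.Series(np.linspace(-1, 1, cfg.n_birds), index=idx)
        a, _, _ = synthetic.simulate_breeding(cfg, scores)
        b, _, _ = synthetic.simulate_breeding(cfg, scores)
        pd.testing.assert_frame_equal(a, b)

    def test_sex_specific_slope_sign_recovered(self):
        """A male-negative score effect on fledging shows up with the right
        sign in a sex-stratified logistic fit in most replicates."""
        hits = 0
        n_rep = 10
        for rep in range(n_rep):
            cfg = SimConfig(seed=100 + rep, n_birds=60,
                            fledging_effects=FledgingEffects(
                                intercept=0.3, score=0.4, ssta=0.8,
                                score_sex=-0.8))
            rng = np.random.default_rng(200 + rep)
            idx = [f"bird{b:03d}" for b in range(cfg.n_birds)]
            scores = pd.Series(rng.normal(0, 1.3, cfg.n_birds), index=idx)
            breeding, _, _ = synthetic.simulate_breeding(cfg, scores)
            males = breeding[breeding["sex"] == "male"]
            s = males["bird_id"].map(scores).to_numpy()
            fit = models.fit_glm_binomial(
                males["success"].to_numpy(float),
                np.column_stack([np.ones(len(males)), s]),
                xnames=["intercept", "score"])
            hits += fit.params["score"] < 0  # true male slope 0.4-0.8 < 0
        assert hits >= 0.9 * n_rep


class TestWriters:
    def test_gps_csv_round_trip(self, tmp_path, sim_config):
        gps, _ = synthetic.simulate_gps(sim_config)
        p = tmp_path / "gps.csv"
        synthetic.write_gps_csv(gps, p)
        back = tracks.read_gps_csv(p)
        assert len(back) == len(gps)
        np.testing.assert_allclose(
            back.sort_values(["bird_id", "timestamp"])["lat"].to_numpy(),
            gps.sort_values(["bird_id", "timestamp"])["lat"].to_numpy(), atol=1e-9)

    def test_fishing_csv_round_trip(self, tmp_path):
        df = synthetic.simulate_fishing_events(SimConfig(seed=30, n_birds=2))
        p = tmp_path / "f.csv"
        synthetic.write_fishing_csv(df, p)
        back = spatial.read_fishing_csv(p)
        assert len(back) == len(df)
        assert (back["haul_end"] == df["haul_end"].dt.floor("s")).all()
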