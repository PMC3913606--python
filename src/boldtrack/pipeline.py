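"""End-to-end orchestration: simulate -> trips -> FPT/ARS -> habitat ->
fisheries -> personality scores -> repeatability -> fitness.

Every stage reads and writes flat CSV/JSON artefacts in a run directory so
each step is runnable standalone and inspectable; a manifest with per-stage
record counts (fixes read, trips kept, trips excluded by phase, ARS zones,
overlapping trips) is written before exit on success or failure — exclusion
bookkeeping is a first-class output of a tracking study.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__, fpt, models, personality, spatial, synthetic, tracks

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """All stage parameters, with the study's defaults."""

    colony_lat: float = -48.4
    colony_lon: float = 68.4
    buffer_km: float = 2.0
    min_trip_fixes: int = 5
    speed_threshold_kmh: float = 10.0
    step_km: float = 1.0
    rmin_km: float = 1.0
    rmax_km: float = 100.0
    min_sep_km: float = 10.0
    shelf_depth_m: float = 200.0
    oceanic_depth_m: float = 2000.0
    discard_radius_km: float = 19.0
    discard_window_h: float = 1.0
    phase: str = "brooding"
    seed: int = 0
    outdir: str = "runs/out"
    write_fpt_profiles: bool = False  # per-point FPT tables are large
    sim: dict = field(default_factory=dict)  # overrides for SimConfig

    @property
    def colony(self):
        return (self.colony_lat, self.colony_lon)

    @property
    def radii(self):
        return np.arange(self.rmin_km, self.rmax_km + 0.5 * self.step_km, 1.0)

    @classmethod
    def from_yaml(cls, path):
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config key(s): {sorted(unknown)}")
        return cls(**raw)

    def sim_config(self) -> synthetic.SimConfig:
        kwargs = dict(self.sim)
        eff = kwargs.pop("fledging_effects", None)
        if isinstance(eff, dict):
            kwargs["fledging_effects"] = synthetic.FledgingEffects(**eff)
        return synthetic.SimConfig(
            seed=self.seed, colony=(self.colony_lat, self.colony_lon), **kwargs
        )

    def config_hash(self) -> str:
        payload = json.dumps(dataclasses.asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


# ---------------------------------------------------------------------------
# stages


def stage_simulate(cfg: PipelineConfig) -> dict:
    """Generate every pipeline input with recorded ground truth."""
    out = Path(cfg.outdir)
    out.mkdir(parents=True, exist_ok=True)
    sim = cfg.sim_config()
    gps, patch_truth = synthetic.simulate_gps(sim, phase=cfg.phase)
    synthetic.write_gps_csv(gps, out / "gps.csv")
    grid = synthetic.simulate_bathymetry(sim)
    spatial.write_bathymetry(grid, out / "bathymetry.asc")
    # vessels operate over the period the birds are actually at sea
    t0, t1 = gps["timestamp"].min(), gps["timestamp"].max()
    fishing = synthetic.simulate_fishing_events(
        sim, window=(t0.floor("D"), (t1 + pd.Timedelta(hours=12)).ceil("D"))
    )
    synthetic.write_fishing_csv(fishing, out / "fishing.csv")
    behaviour, latent = synthetic.simulate_behaviour(sim)
    beh_out = behaviour.copy()
    beh_out["date"] = beh_out["date"].dt.strftime("%Y-%m-%d")
    beh_out.to_csv(out / "behaviour.csv", index=False)
    sexes = synthetic.simulate_sexes(sim)
    ssta = synthetic.simulate_ssta(sim)
    scores = pd.Series(latent["bird"])
    scores = scores - scores.mean()
    breeding, ssta, fledge_truth = synthetic.simulate_breeding(sim, scores, sexes, ssta)
    breeding.to_csv(out / "breeding.csv", index=False)
    ssta.to_csv(out / "ssta.csv", index=False)
    pd.DataFrame({"bird_id": list(sexes), "sex": list(sexes.values())}).to_csv(
        out / "birds.csv", index=False
    )
    truth = synthetic.GroundTruth(
        patches=patch_truth,
        boldness_latent=latent["bird"],
        icc_boldness=sim.icc_boldness,
        fledging_effects=fledge_truth["fledging_effects"],
        ssta_by_year=fledge_truth["ssta_by_year"],
        sexes=sexes,
    )
    truth.to_json(out / "ground_truth.json")
    return {"fixes_written": len(gps), "fishing_events": len(fishing),
            "behaviour_tests": len(behaviour), "breeding_records": len(breeding)}


def stage_trips(cfg: PipelineConfig):
    out = Path(cfg.outdir)
    gps = tracks.read_gps_csv(out / "gps.csv")
    all_trips = tracks.segment_trips(gps, cfg.colony, buffer_km=cfg.buffer_km,
                                     min_fixes=cfg.min_trip_fixes)
    kept = tracks.filter_phase(all_trips, cfg.phase, strict=False)
    metrics = tracks.metrics_table(kept, cfg.colony)
    metrics.to_csv(out / "trip_metrics.csv", index=False)
    counts = {"fixes_read": len(gps), "trips_segmented": len(all_trips),
              "trips_excluded_by_phase": len(all_trips) - len(kept),
              "trips_kept": len(kept)}
    return kept, metrics, counts


def stage_fpt(cfg: PipelineConfig, trips: list[tracks.Trip]):
    """Speed filter, FPT sweep, peak/threshold, ARS zone extraction."""
    out = Path(cfg.outdir)
    zone_rows, peak_rows, profile_frames = [], [], []
    n_unusable = 0
    for trip in trips:
        filt = tracks.filter_on_water(tracks.compute_speeds(trip),
                                      cfg.speed_threshold_kmh)
        if not filt.usable_for_fpt:
            n_unusable += 1
            continue
        path, profile, peak, zones = fpt.analyse_trip(
            filt, step_km=cfg.step_km, radii_km=cfg.radii, min_sep_km=cfg.min_sep_km
        )
        if cfg.write_fpt_profiles and profile is not None:
            pf = pd.DataFrame(
                profile.fpt_h,
                columns=[f"fpt_h_r{r:g}km" for r in profile.radii_km])
            pf.insert(0, "trip_id", trip.trip_id)
            pf.insert(1, "point", np.arange(len(pf)))
            profile_frames.append(pf)
        if peak is not None:
            peak_rows.append({"trip_id": trip.trip_id, "bird_id": trip.bird_id,
                              "radius_km": peak.radius_km, "variance": peak.variance,
                              "threshold_h": peak.threshold_h})
        for zi, z in enumerate(zones):
            zone_rows.append({"trip_id": trip.trip_id, "bird_id": trip.bird_id,
                              "zone": zi, "centre_lat": z.centre[0],
                              "centre_lon": z.centre[1], "mean_fpt_h": z.mean_fpt_h,
                              "n_points": len(z.member_idx)})
    zones_df = pd.DataFrame(zone_rows, columns=["trip_id", "bird_id", "zone",
                                                "centre_lat", "centre_lon",
                                                "mean_fpt_h", "n_points"])
    peaks_df = pd.DataFrame(peak_rows, columns=["trip_id", "bird_id", "radius_km",
                                                "variance", "threshold_h"])
    zones_df.to_csv(out / "ars_zones.csv", index=False)
    peaks_df.to_csv(out / "fpt_peaks.csv", index=False)
    if cfg.write_fpt_profiles and profile_frames:
        pd.concat(profile_frames, ignore_index=True).to_csv(
            out / "fpt_profiles.csv", index=False)
    counts = {"trips_unusable_for_fpt": n_unusable, "ars_zones": len(zones_df)}
    return zones_df, peaks_df, counts


def stage_personality(cfg: PipelineConfig, metrics: pd.DataFrame):
    out = Path(cfg.outdir)
    beh = pd.read_csv(out / "behaviour.csv", parse_dates=["date"])
    bold_pca = personality.pca_correlation(beh, personality.BOLDNESS_VARS,
                                           sign_anchor=personality.SIGN_ANCHOR["boldness"])
    beh = beh.assign(pc1=personality.project_pc1(bold_pca, beh))
    boldness = personality.individual_boldness(beh)
    forage_pca = personality.pca_correlation(metrics, personality.FORAGING_VARS,
                                             sign_anchor=personality.SIGN_ANCHOR["foraging"])
    metrics = metrics.assign(pc1=personality.project_pc1(forage_pca, metrics))
    foraging = personality.individual_foraging_score(metrics)
    rho, p = personality.score_correlation(boldness, foraging)
    boldness.rename_axis("bird_id").reset_index().to_csv(out / "boldness.csv", index=False)
    foraging.rename_axis("bird_id").reset_index().to_csv(out / "foraging_scores.csv", index=False)
    pca_summary = {
        "boldness": {"eigenvalues": bold_pca.eigenvalues.tolist(),
                     "pc1_proportion": float(bold_pca.proportion_variance[0])},
        "foraging": {"eigenvalues": forage_pca.eigenvalues.tolist(),
                     "pc1_proportion": float(forage_pca.proportion_variance[0])},
        "spearman_rho": rho, "spearman_p": p,
    }
    with open(out / "personality_summary.json", "w") as fh:
        json.dump(pca_summary, fh, indent=1)
    return {"behaviour": beh, "boldness": boldness, "trip_pc1": metrics,
            "foraging": foraging, "bold_pca": bold_pca, "forage_pca": forage_pca,
            "rho": rho, "rho_p": p}


def stage_repeatability(cfg: PipelineConfig, scores: dict, n_boot: int = 200):
    beh = scores["behaviour"]
    trip_pc1 = scores["trip_pc1"]
    fitb = models.fit_lmm_random_intercept(
        beh["pc1"], np.ones((len(beh), 1)), beh["bird_id"], xnames=["intercept"]
    )
    rng = np.random.default_rng(cfg.seed + 101)
    rep_bold = models.repeatability(fitb, n_boot=n_boot, rng=rng)
    fitf = models.fit_lmm_random_intercept(
        trip_pc1["pc1"], np.ones((len(trip_pc1), 1)), trip_pc1["bird_id"],
        xnames=["intercept"],
    )
    rep_forage = models.repeatability(fitf, n_boot=n_boot, rng=rng)
    return {"boldness": rep_bold, "foraging": rep_forage}


def _sex_lookup(cfg: PipelineConfig) -> pd.Series:
    birds = pd.read_csv(Path(cfg.outdir) / "birds.csv")
    return birds.set_index("bird_id")["sex"]


def _sex_test(trip_pc1: pd.DataFrame, sexes: pd.Series):
    """LRT for a sex difference in trip PC1 (bird as random intercept)."""
    df = trip_pc1.join(sexes, on="bird_id").dropna(subset=["sex"])
    male = (df["sex"] == "male").to_numpy(float)
    X1 = np.column_stack([np.ones(len(df)), male])
    full = models.fit_lmm_random_intercept(df["pc1"], X1, df["bird_id"],
                                           xnames=["intercept", "sex"])
    red = models.fit_lmm_random_intercept(df["pc1"], np.ones((len(df), 1)),
                                          df["bird_id"], xnames=["intercept"])
    return models.lrt(full, red, term="sex")


def stage_habitat(cfg: PipelineConfig, zones_df: pd.DataFrame, boldness: pd.Series):
    """Habitat class at ARS-zone centres; ordinal regression of habitat on
    boldness and sex with trip-within-bird random intercepts."""
    out = Path(cfg.outdir)
    grid = spatial.read_bathymetry(out / "bathymetry.asc")
    sexes = _sex_lookup(cfg)
    df = zones_df.copy()
    df["depth_m"] = [float(grid.depth_at(la, lo))
                     for la, lo in zip(df["centre_lat"], df["centre_lon"])]
    df["habitat"] = [spatial.classify_habitat(d) for d in df["depth_m"]]
    df = df.dropna(subset=["habitat"])
    df["boldness"] = df["bird_id"].map(boldness)
    df["sex"] = df["bird_id"].map(sexes)
    df.to_csv(out / "ars_habitat.csv", index=False)
    dm = df.dropna(subset=["boldness", "sex"])
    ycodes = pd.Categorical(dm["habitat"], categories=spatial.HABITAT_ORDER,
                            ordered=True).codes
    results = {"data": df}
    if len(dm) >= 10 and len(np.unique(ycodes)) >= 2:
        male = (dm["sex"] == "male").to_numpy(float)
        b = dm["boldness"].to_numpy(float)
        X_full = np.column_stack([b, male])
        t_bold, full, _ = models.ordinal_term_test(
            ycodes, X_full, ["boldness", "sex"], "boldness",
            groups=dm["bird_id"], groups2=dm["trip_id"])
        t_sex, full2, _ = models.ordinal_term_test(
            ycodes, X_full, ["boldness", "sex"], "sex",
            groups=dm["bird_id"], groups2=dm["trip_id"])
        results["boldness"] = t_bold
        results["sex"] = t_sex
        results["fit"] = full if full.loglik >= full2.loglik else full2
    else:
        logger.warning("habitat model skipped: too few classified ARS zones")
    return results


def stage_fisheries(cfg: PipelineConfig, trips: list[tracks.Trip],
                    scores: dict):
    """Discarding-zone overlap bookkeeping and fix-level binomial GLMMs."""
    out = Path(cfg.outdir)
    events = spatial.read_fishing_csv(out / "fishing.csv")
    zones = spatial.build_discarding_zones(events, cfg.discard_radius_km,
                                           cfg.discard_window_h)
    sexes = _sex_lookup(cfg)
    rows, fix_frames = [], []
    for trip in trips:
        any_ov, prop, hours = spatial.trip_overlap_summary(trip, zones)
        rows.append({"trip_id": trip.trip_id, "bird_id": trip.bird_id,
                     "any_overlap": any_ov, "prop_fixes": prop,
                     "hours_at_vessels": hours})
        flags = spatial.overlap_flags(trip, zones)
        fix_frames.append(pd.DataFrame({"trip_id": trip.trip_id,
                                        "bird_id": trip.bird_id,
                                        "overlap": flags.astype(int)}))
    summary = pd.DataFrame(rows)
    summary.to_csv(out / "fisheries_overlap.csv", index=False)
    results = {"summary": summary, "stats": spatial.summarise_overlap(summary)}
    fixes = pd.concat(fix_frames, ignore_index=True) if fix_frames else pd.DataFrame()
    for name in ("boldness", "foraging"):
        score = scores[name]
        dm = fixes.copy()
        dm["score"] = dm["bird_id"].map(score)
        dm["sex"] = dm["bird_id"].map(sexes)
        dm = dm.dropna(subset=["score", "sex"])
        if len(dm) < 50 or dm["overlap"].nunique() < 2:
            logger.warning("fisheries model for %s skipped (insufficient data)", name)
            continue
        male = (dm["sex"] == "male").to_numpy(float)
        s = dm["score"].to_numpy(float)
        y = dm["overlap"].to_numpy(float)
        ones = np.ones(len(dm))
        test, _, _ = models.glmm_binomial_term_test(
            y, np.column_stack([ones, s, male]), ["intercept", "score", "sex"],
            "score", groups=dm["bird_id"], groups2=dm["trip_id"])
        results[name] = models.LRTResult(chi2=test.chi2, df=test.df,
                                         p=test.p, term=name)
    return results


def stage_fitness(cfg: PipelineConfig, scores: dict):
    out = Path(cfg.outdir)
    breeding = pd.read_csv(out / "breeding.csv")
    ssta = pd.read_csv(out / "ssta.csv").set_index("year")["ssta"]
    results = {}
    for name in ("boldness", "foraging"):
        score = scores[name]
        results[name] = models.fitness_analysis(breeding, score, ssta,
                                                score_name=name)
        curves = models.prediction_curves(results[name]["full"])
        curves.to_csv(out / f"fitness_curves_{name}.csv", index=False)
        year0 = breeding[breeding["year"] == breeding["year"].max()]
        try:
            results[f"{name}_single_year"] = models.single_year_fitness(year0, score)
        except (models.SeparationError, ValueError) as err:
            logger.warning("single-year fitness for %s skipped: %s", name, err)
    return results


# ---------------------------------------------------------------------------
# run-all


def _lrt_row(t: models.LRTResult) -> dict:
    return {"chi2": round(t.chi2, 3), "df": t.df, "p": round(t.p, 4)}


def run_all(cfg: PipelineConfig, simulate: bool = True, n_boot: int = 200) -> dict:
    """Execute every stage in order, writing artefacts, a one-row-per-test
    summary table and a manifest (always written, success or failure)."""
    out = Path(cfg.outdir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = {"config_hash": cfg.config_hash(), "version": __version__,
                "seed": cfg.seed, "started": str(pd.Timestamp.utcnow()),
                "counts": {}, "status": "running", "failed_stage": None}

    def _write_manifest():
        manifest["finished"] = str(pd.Timestamp.utcnow())
        with open(out / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=1, default=str)

    summary_rows: list[dict] = []
    results: dict = {"manifest": manifest}
    stage = "simulate"
    try:
        if simulate:
            manifest["counts"].update(stage_simulate(cfg))

        stage = "trips"
        trips, metrics, counts = stage_trips(cfg)
        manifest["counts"].update(counts)

        stage = "fpt"
        zones_df, peaks_df, counts = stage_fpt(cfg, trips)
        manifest["counts"].update(counts)

        stage = "personality"
        scores = stage_personality(cfg, metrics)
        results["personality"] = scores
        sexes = _sex_lookup(cfg)
        summary_rows.append({"response": "boldness",
                             "term": "sex",
                             **_lrt_row(_sex_test(scores["behaviour"], sexes))})
        summary_rows.append({"response": "foraging personality score",
                             "term": "sex",
                             **_lrt_row(_sex_test(scores["trip_pc1"], sexes))})

        stage = "repeatability"
        reps = stage_repeatability(cfg, scores, n_boot=n_boot)
        results["repeatability"] = reps

        stage = "habitat"
        hab = stage_habitat(cfg, zones_df, scores["boldness"])
        results["habitat"] = hab
        for term in ("boldness", "sex"):
            if term in hab:
                summary_rows.append({"response": "foraging habitat",
                                     "term": term, **_lrt_row(hab[term])})

        stage = "fisheries"
        fish = stage_fisheries(cfg, trips, scores)
        results["fisheries"] = fish
        manifest["counts"]["trips_overlapping_fisheries"] = fish["stats"]["trips_overlapping"]
        for term in ("boldness", "foraging"):
            if term in fish:
                summary_rows.append({"response": "fisheries overlap",
                                     "term": term, **_lrt_row(fish[term])})

        stage = "fitness"
        fit = stage_fitness(cfg, scores)
        results["fitness"] = fit
        for name in ("boldness", "foraging"):
            if name in fit:
                summary_rows.append({
                    "response": "reproductive success (multi-year)",
                    "term": f"{name} x sex x SSTa",
                    **_lrt_row(fit[name]["interaction_test"]),
                })
            sy = fit.get(f"{name}_single_year")
            if sy:
                summary_rows.append({"response": "reproductive success (single year)",
                                     "term": name, **_lrt_row(sy["score"])})
                summary_rows.append({"response": "reproductive success (single year)",
                                     "term": f"{name} x sex",
                                     **_lrt_row(sy["score:sex"])})

        manifest["status"] = "ok"
    except Exception as err:
        manifest["status"] = "failed"
        manifest["failed_stage"] = stage
        manifest["error"] = f"{type(err).__name__}: {err}"
        _write_manifest()
        raise
    summary = pd.DataFrame(summary_rows,
                           columns=["response", "term", "chi2", "df", "p"])
    summary.to_csv(out / "summary_table.csv", index=False)
    (out / "summary_table.txt").write_text(summary.to_string(index=False) + "\n")
    rep_json = {
        name: {"r": r.r, "se": r.se, "ci": r.ci, "p": r.p}
        for name, r in results["repeatability"].items()
    }
    with open(out / "repeatability.json", "w") as fh:
        json.dump(rep_json, fh, indent=1)
    with open(out / "fisheries_stats.json", "w") as fh:
        json.dump(results["fisheries"]["stats"], fh, indent=1)
    _write_manifest()
    results["summary"] = summary
    return results
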