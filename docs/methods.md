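# Methods

This note documents the models and procedures `boldtrack` implements, the
numerical choices behind them, what the synthetic colony does and does not
emulate, and the known limitations.

## Overview

The package reconstructs a complete behavioural-ecology analysis chain for
a GPS-tracked, colony-breeding seabird (the motivating system is a
black-browed albatross colony on the Kerguelen shelf at 48.4°S, 68.4°E):

1. **Tracks** — ingest 2-minute GPS fixes, segment them into
   colony-to-colony foraging trips, and compute four trip-effort metrics
   (duration, foraging range, northerly and southerly latitude extents).
2. **FPT/ARS** — locate area-restricted search (ARS) with first-passage
   time (FPT) analysis on speed-filtered, 1-km-interpolated tracks.
3. **Spatial context** — classify ARS-zone habitat from bathymetry
   (shelf < 200 m, shelf edge 200–2000 m, oceanic > 2000 m) and flag
   per-fix overlap with longline discarding zones (19 km around the
   haul-end point, open for one hour).
4. **Personality scores** — collapse novel-object ethogram counts and the
   trip metrics to PC1 of their correlation matrices; extract per-bird
   mean-centred *boldness* and *foraging personality* from fixed-effect
   linear models; correlate them (Spearman).
5. **Statistical models** — repeatability (ICC) by ML variance
   partitioning with parametric-bootstrap uncertainty; binomial and
   proportional-odds mixed models; ANOVA-style likelihood-ratio tests
   (LRT); breeding-success models with score × sex × SSTa interactions.

Because no field data accompany the analysis, a first-class synthetic
module generates every input with recorded ground truth, and the test
suite validates each stage by recovering what was planted.

## Trip segmentation and metrics

A trip is a maximal run of consecutive fixes more than `buffer_km` (2 km)
from the colony; runs shorter than 5 fixes are discarded as GPS jitter
(the threshold is configurable; the field protocol is silent on it). A
trip is *complete* when flanked by inside-buffer fixes. Latitudes are
signed decimal degrees (south negative); the "northerly extent" is the
maximum signed latitude and the "southerly extent" the absolute value of
the minimum, so both increase with excursion in their direction at this
southern-hemisphere colony. Distances use the spherical haversine formula
with R = 6371.0 km; the sub-0.5 % spheroid error is immaterial at
trip scales. Per-fix speed is the distance from the previous fix over the
elapsed time; fixes slower than 10 km/h are removed before FPT analysis,
since birds sitting on the water drift sinuously without foraging.

## First-passage time and ARS zones

FPT at a point for radius *r* is the time between the first backward and
first forward exits from the circle of radius *r* centred there. Tracks
are re-sampled every 1 km of along-path distance (positions and times
linearly interpolated between fixes) and FPT is evaluated at every path
point for radii 1–100 km. Crossing times are refined by bisecting the
great-circle distance along the linearly-interpolated crossing segment;
distance to a fixed centre is convex along a straight segment, so the
root is unique and exit detection via the running maximum of vertex
distances is exact. Points whose circle is never exited in one of the two
directions have undefined FPT and are excluded (not imputed).

The search scale is the radius maximising the variance of log FPT across
points (natural log; the base shifts the curve by a constant and cannot
move the peak). Peaks are local maxima that exceed 10 % of the curve
maximum; ties break toward the smaller radius; up to two peaks are
reported and downstream stages use the largest. An absolute variance
floor of 0.05 (log-hours²) guards against structureless tracks: a pure
commute at near-constant speed has FPT ≈ 2r/v everywhere and its residual
variance is an order of magnitude below the floor, while a planted patch
raises the peak variance above ~0.5.

The FPT threshold separating ARS from transit at the peak radius is the
exact Otsu split of log FPT (the two-group split maximising between-class
variance, computed by prefix sums over the sorted sample, identical to
exhaustive search). The originating literature leaves the threshold rule
unspecified; Otsu was chosen because it is parameter-free and reproduces
the intended bimodal separation between patch-dwelling and commuting
points. Contiguous above-threshold runs form candidate zones; zones whose
centres (arithmetic mean member position) are within 10 km are merged
until stable. "10 km apart" is read as centre-to-centre separation.

One geometric caveat, found while validating the null case: a
colony-return trip necessarily doubles FPT at its distal turnaround,
because the circle there covers both the outbound and inbound legs. On
patch-free out-and-back simulations the detector therefore flags a small
distal zone in most replicates (mean ARS fraction ≈ 0.19 of the path,
within the ≤ 0.20 specificity bound), while one-way patch-free segments
yield no zones at all. Real analyses should expect the distal-point zone:
in the field the distal point usually *is* a foraging destination.

## Habitat and fisheries overlap

Habitat at an ARS-zone centre is the nearest-cell depth of an ESRI ASCII
bathymetry grid (no bilinear interpolation — smoothing across the shelf
break would manufacture intermediate depths that belong to no water mass).
Boundary depths of exactly 200 m and 2000 m are assigned to the shelf
edge (closed interval). Grid boundary ties resolve to the lower stored
row/column index.

Each longline event contributes one discarding zone: a 19 km radius
around the end-of-hauling position (the fastest a steaming longliner can
travel in the hour over which discarding happens), open for exactly
[haul end, haul end + 1 h], closed at both ends. A fix overlaps if it is
inside any zone's radius and window; overlap is monotone in both buffer
sizes. Only discarding zones are modelled — attendance during setting or
hauling is rare for this fishery and excluded from the analysed exposure.

## Personality scores

Both scores are PC1 of a correlation-matrix (standardised) PCA — the
variables are on incommensurate scales (counts, seconds, km, hours), so
covariance PCA would just rank them by variance. Eigenvalues therefore
sum to the number of variables and PC1's share of variance is
eigenvalue/p. PC1's sign is anchored so pecking (boldness) and foraging
range (foraging score) load positive; other components orient their
largest loading positive, making the decomposition invariant to row
order. Rows with missing cells are dropped; a constant column is an
error.

Per-bird boldness comes from an ordinary least-squares fit of the
observation score on observation number, date (numeric day of season) and
bird identity with sum-to-zero contrasts, so the covariate effects stay
identifiable; the bird effects are then mean-centred. With ~10 % of birds
tested twice, the date slope is nearly collinear with observation number
and is estimated with large variance — retained anyway, as the protocol
prescribes, and the recovery tests average over replicates accordingly.
Per-bird foraging score is the fixed-effect fit of trip PC1 on bird
identity, which for this one-factor design equals the per-bird mean (the
equivalence is asserted at runtime). Only brooding-phase trips enter the
foraging PCA; incubation trips are systematically longer and would
dominate PC1.

## Mixed models and tests

All fits are ML (never REML) because every hypothesis test is a full
vs. reduced likelihood-ratio comparison across fixed-effect structures.

* **Gaussian LMM** (one random intercept): the likelihood is profiled
  over the between/within variance ratio — closed-form GLS for the fixed
  effects and residual variance given the ratio, bounded scalar search on
  the log-ratio (tolerance 1e-10), boundary (ratio 0 = OLS) checked
  explicitly. Verified against statsmodels MixedLM (ML) to ~1e-9 in
  log-likelihood.
* **Repeatability** r = σ²_bird / (σ²_bird + σ²_res). Standard error and
  95 % CI by parametric bootstrap (simulate from the fitted model, refit,
  percentile interval; 1000 draws by default). The p-value tests
  σ²_bird = 0 with the 50:50 χ²₀/χ²₁ boundary mixture. Boundary estimates
  are reported as exact zeros.
* **Binomial GLM**: statsmodels IRLS behind the package surface, with
  complete-separation detection (error, not silently diverging
  coefficients).
* **Binomial GLMM**: one random intercept is integrated by adaptive
  Gauss–Hermite quadrature (15 nodes, re-centred and re-scaled at each
  group's conditional mode found by damped Newton with backtracking);
  validated against 201-node integration to < 1e-6. Two factors (nested
  trip-in-bird, or crossed bird × year) use a Laplace approximation with
  a joint Newton solve over all intercepts (dense Hessian assembled by
  bincount; backtracking line search). For Bernoulli data the Laplace
  total-log-likelihood error is O(1/group size) per group — about 2–8
  × 10⁻³ per group in our regimes — which is ample for LRTs on fixed
  effects but is why the single-factor path defaults to quadrature.
  Random-intercept SDs are capped at 5 logit units: beyond that the
  group effect saturates the response and the surface degenerates
  (quasi-separated data hit this cap and are flagged).
* **Ordinal (proportional odds)**: cumulative logit ML with monotone
  threshold parameterisation (first threshold free, positive increments
  on the log scale), optional random intercepts as above. Checked against
  statsmodels OrderedModel and against the closed-form null (thresholds =
  logits of cumulative frequencies).
* **LRT**: χ² = 2Δll with df = parameter-count difference; full models in
  nested comparisons are warm-started at the reduced optimum (dropped
  coefficients at zero), so optimiser noise cannot produce a negative
  statistic; genuine numerical negatives are clamped to zero with a
  warning.
* **Fitness analysis**: fledging (0/1) on the logit scale with the full
  score × sex × SSTa structure and crossed random intercepts for bird and
  year. The headline 4-df test drops {score:sex, score:SSTa, sex:SSTa,
  score:sex:SSTa} — the unique 4-df set matching an "interaction between
  sex, year quality and score". SSTa enters continuously; the tercile
  bands (boundaries −0.36 and −0.15 °C) are used only for stratified
  prediction curves. The single-season analysis (one record per bird)
  uses a plain GLM, since a bird-level intercept is not identifiable
  from one Bernoulli draw each.

Calibration at the study design (59 birds × 23 years): the 4-df null
rejection rate is ~4.8 % over 400 replicates, and the boundary-mixture
repeatability test ~5.0 % over 400; planted sex-opposite score effects
(female slope +0.4, male −0.4 on the logit scale) are detected in
essentially all replicates.

## The synthetic colony

`SimConfig` defaults are the study conditions: colony at (−48.4, 68.4),
fixes every 120 s, 59 birds × 2 brooding trips, 23 breeding seasons,
latent boldness ICC 0.5 with ~10 % of birds retested, balanced sex ratio.

* **Movement** is a two-state correlated random walk: commuting at
  45 km/h with von Mises turning concentration 60 toward the target, and
  patch search at 15 km/h with concentration 1 (soft-reflected back into
  the patch), dwelling 5 h per patch. Commute speed matches albatross
  travel flight; search speed stays above the 10 km/h on-water filter so
  planted foraging survives the speed filter (drifting on the water is
  not separately simulated).
* **Individual structure**: one standard-normal latent axis per bird
  drives the nest-defence counts *and* (negated, mixed at strength 0.4
  with an independent bird effect) the preferred patch distance — bolder
  birds forage nearer the colony, giving a planted behavioural syndrome
  with realised rank correlation ≈ −0.3. Patch preferences (distance
  60–350 km, an individual mean bearing) plus within-bird trip scatter
  (SD 80 km, 30°) put the between-bird share of trip-distance variance
  near 0.5, the foraging-repeatability regime of interest.
* **Bathymetry** is radially symmetric: ~50 m at the colony, 200 m at
  100 km, 2000 m at 300 km, deepening 5 m/km beyond — monotone along any
  transect, with all three habitat classes well represented over the
  trip range.
* **Fishing events**: 60 longline sets during the tracking window with
  haul-end points in the shelf-edge depth band. Simulated birds do not
  seek vessels, so overlap is incidental corridor-crossing (a few
  per cent of trips) — appropriate for testing bookkeeping and the null
  overlap models, but weaker than the attraction-driven overlap real
  colonies show.
* **Behaviour counts**: Poisson with log-rate linear in the latent value
  (pecks, lunges, vocalisations positive; snaps negative) and a bounded
  logistic transform for seconds sitting. The count channel attenuates
  the latent ICC (0.9 on the latent scale reads out near 0.6–0.7 on PC1
  of counts) — exactly the attenuation a real ethogram instrument
  introduces — so estimator-calibration tests run on the recorded
  latent-observation scale, and instrument attenuation is tested
  qualitatively.
* **Breeding**: yearly SSTa drawn uniformly within the three tercile
  ranges (bands balanced over 23 years); fledging Bernoulli with
  configurable log-odds coefficients over score, sex, SSTa and their
  interactions; all planted values recorded in the ground-truth JSON.

Randomness is fully reproducible: a single root seed spawns named
substreams per generator and per bird/trip, so any artefact can be
regenerated in isolation.

What the generator does **not** emulate: device loss and fix gaps (the
loggers' real gap statistics are unreported), winds and currents,
prey-field dynamics, vessel attraction, observation error in positions,
and carry-over effects between years. Passing tests demonstrate that the
pipeline recovers planted signal under these idealised conditions, not
that field data meet them.

## Validation problem sizes

The validation suite (also run by `scripts/acceptance.py`) uses: 100
random tracks (3 points × 2 radii each) for the FPT brute-force oracle at
0.01 km resampling; 50 replicates for ARS recovery (one 5 km patch per
trip); 50 recovery and 400 null replicates for repeatability at a ~40
birds / 73 trips design; 3 datasets of 20 groups × 15 for the quadrature
oracle; 400 null and 50 powered replicates of the 59 × 23 fitness design
for LRT calibration and power.

## Known limitations

* The Laplace route for multi-factor GLMMs shares the usual small-cluster
  bias of that approximation; with ≤ 3 observations per group prefer the
  single-factor quadrature path or aggregate.
* Quasi-separated overlap data (a handful of positive trips) drive the
  trip-level random-intercept variance to its cap; the fit is flagged,
  and the resulting LRTs should be read as descriptive.
* Nearest-cell bathymetry lookup means zone centres within half a cell of
  the shelf break can be classified either way; at 0.1° cells this is a
  ~5 km ambiguity, comparable to zone-centre uncertainty itself.
* The FPT threshold rule (exact Otsu) is one defensible choice among
  several; a quantile alternative is available via the module API, and
  threshold choice mainly moves zone boundaries, not zone existence.
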