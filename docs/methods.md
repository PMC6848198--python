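# Methods

`krillhab` implements an end-to-end analysis linking the characteristics of
Antarctic krill (*Euphausia superba*) swarms, measured with a calibrated
38/120 kHz scientific echosounder, to the presence of Antarctic blue whales
(*Balaenoptera musculus intermedia*) located by visual sighting and
paired-sonobuoy triangulation. This note documents the models, the
parameters that matter, the synthetic survey generator, and the numerical
and design choices.

## 1. Echogram cleaning (`krillhab.clean`)

Raw volume backscattering strength Sv(ping, depth) at both frequencies is
cleaned in three steps.

**Background / TVG noise removal** follows the echo-integration approach of
De Robertis & Higginbottom (2007). Received power is recovered by stripping
the time-varied gain, `P = Sv − (20·log10 r + 2αr)`, averaged in the linear
domain over cells (default 10 pings × 5 m), and the per-interval noise level
is the minimum cell mean over depth. That noise, re-amplified by the TVG, is
subtracted from Sv in the linear domain; samples with SNR below a gate
(default 10 dB) become the no-data sentinel (−999 dB). The cited method
leaves cell size and gate to the operator; both are configurable here.
Sentinel samples count as zero power in the noise estimate — they carry no
energy — which also makes the removal idempotent: a second pass re-estimates
near-zero noise instead of mistaking residual signal for noise. Absorption
defaults (0.010 dB m⁻¹ at 38 kHz, 0.027 dB m⁻¹ at 120 kHz) are
representative of cold Southern Ocean water and configurable.

**Exclusion zones**: samples above the 10 m surface exclusion, below the
250 m analysis limit, or below an optional per-ping bottom line are masked.

**Smoothing**: a 7 × 7 mean filter applied in the linear domain (intensities
are physically additive; whether the original analysis smoothed in the
linear or dB domain is not stated — linear is our choice and is flagged
here). Sentinel samples are excluded from each kernel mean by mask-aware
renormalisation. Kernel counts are rounded back to integer multiples of
1/49 before a cell is treated as covered: the separable sliding-window
accumulator otherwise leaves ~10⁻¹³ residues after large swarm values pass,
and the tiny-sum/tiny-count division fabricates ghost samples in fully
masked columns.

## 2. Swarm delineation and classification (`krillhab.detect`)

Aggregations are delineated on the 120 kHz channel with a SHAPES-style
threshold–link–filter chain (Barange 1994): threshold (default −70 dB re
1 m⁻¹), 4-connected components as candidates, merge candidates whose
edge-to-edge gaps are within the linking distances (defaults 15 m
horizontal, 5 m vertical), discard regions failing the minimum length
(15 m) or height (5 m). The published analysis defers the exact parameter
values to prior krill studies; the defaults here follow that literature and
every value is configurable. On sample grids the gap condition reduces to an
integer form (`|Δi| ≤ floor(Lh/dx)+1` etc.), and the production
implementation is verified against an exhaustive brute-force
threshold/link search in randomized tests.

Morphology (length, height, area, perimeter) is measured on the rectilinear
sample footprint in (along-track m, depth m) coordinates; length and height
use outer cell extents. **Beam correction** after Diner (2001): the beam
diameter at mean swarm depth, `D_b = 2·z̄·tan(θ/2)` with θ the nominal 7°
beam width, is subtracted from the measured length, and area/perimeter are
re-measured after shrinking every horizontal row run by `D_b/2` per side.
Diner's full SNR-dependent effective beam angle is reduced to this geometric
default (the SNR inputs are not available); a caller-supplied θ_eff hook is
accepted. Height is not beam-corrected (only horizontal dimensions are
beam-inflated). Regions whose corrected length or corrected area is
non-positive are flagged sub-beam-resolution and excluded from the swarm
table by default.

**Species classification** uses the dual-frequency dB-difference
fingerprint: a region is krill iff `MVBS₁₂₀ − MVBS₃₈` lies in the closed
window [1.04, 14.80] dB, with MVBS the linear-domain mean Sv over the
region's mask.

## 3. Swarm descriptors (`krillhab.characterise`)

Each krill swarm is summarised by 11 covariates: corrected area, corrected
length, corrected perimeter, roughness (corrected perimeter / corrected
area, m⁻¹), mean depth, mean height, dB difference, biomass density,
swarm backscattering coefficient, nearest-neighbour distance and
nearest-neighbour depth difference.

**Biomass density (wet weight)**: `ρ_v = 10^((MVBS₁₂₀ − TS_kg)/10)` where
`TS_kg = TS(L) − 10·log10(m(L) in kg)` is the target strength of 1 kg of
krill at 120 kHz. The default TS(L) is a documented log-linear fit,
`TS = 27.5·log10(L_mm) − 118.9` dB re 1 m², spanning the range of
simplified-SDWBA predictions over the trawled 26–60 mm sizes; any published
curve can be dropped in through the `TSModel` abstraction, which asserts
monotonicity over that range at import. Wet mass follows a Morris-type
allometry `m(mg) = 3.85×10⁻³·L^3.20`. A single survey-wide length (default
44.5 mm, the trawled mean) feeds the model; per-stratum lengths are
supported via configuration. The swarm table reports densities in g m⁻³ by
referencing the TS to 1 g (`TS_g = TS_kg − 30`), the scale on which observed
krill swarm densities span roughly 2–1700 g m⁻³.

**Swarm backscattering coefficient** (m): the terse field definition —
acoustic energy proportional to swarm length — is interpreted as
`(linear mean s_v at 120 kHz) × mean height × corrected length`; the formula
is recorded in output metadata and alternative definitions can be plugged
in.

**Nearest neighbours** are found horizontally (great-circle distance between
centroids, excluding self); the depth difference is taken to that same
neighbour. The separate depth-difference variable is what implies a
horizontal, not 3-D, neighbour search.

## 4. Whale localisation (`krillhab.locate`)

All geodesy is spherical (mean radius 6371.0088 km); the error is metres at
the 12–40 km association scales, far below observational error. Visual
sightings become positions by the direct geodesic problem along the true
bearing `(heading + relative angle) mod 360` at the estimated range.

**Cross-bearing fixes** intersect the two great-circle bearing rays in a
gnomonic projection centred between the buoys. Great circles are exactly
straight in this projection, so the fix is exact up to line-intersection
conditioning; a naive equirectangular tangent plane would carry
meridian-convergence error of order 100 m at 40 km at survey latitudes.
Fixes are rejected when the intersection angle is below 10° (or above its
supplement), when the intersection lies behind either bearing ray, or when
it is more than 200 km from both buoys. Each bearing pair is treated as one
detection; fusing repeated triangulations of one animal is out of scope.

**Solar altitude** uses the low-precision NOAA ephemeris (fractional-year
declination and equation-of-time expansions), accurate to ~0.1°, ample for
the day/night annotation (day iff altitude > 0). At the survey latitude and
date (−65.5°, mid-February) the solar noon and midnight altitudes are ≈ +37°
and ≈ −12°.

## 5. Association and data preparation (`krillhab.associate`)

Swarms detected while the ship's heading was highly variable are removed by
an automated analogue of the original visual track assessment: circular
standard deviation of heading in a centred 10-minute window above 30°.
Swarms outside whale effort — periods when the distance to whales was
measurable, visually or by two simultaneously deployed sonobuoys — are
tagged `none` and excluded from modelling (but reported). Presence at each
of the three nested scales {12 km, 1 h}, {20 km, 2 h}, {40 km, 4 h} is
defined as the existence of a whale detection within both thresholds,
inclusive ("within" is read as ≤); labels are therefore monotone
non-decreasing across scales.

Outlier removal is single-pass: for each covariate j, the 99.5 % quantile
Q is computed on the full table (linear interpolation between order
statistics — the removal count is sensitive to the estimator convention, so
it is recorded), and row i is dropped if X_ij > Q for any j. The train/test
split is proportionally stratified: within each class,
`round(0.75·n_class)` rows (round-half-to-even) go to training after a
seeded shuffle, preserving the presence/absence ratio up to rounding. One
split (one seed) is shared across the three scales.

## 6. The habitat model (`krillhab.habitat`)

Whale presence is modelled as `logit(P(y=1|X)) = f(X)` with gradient-boosted
regression trees on the Bernoulli deviance. The model/results pair follows
the statsmodels convention: `WhaleHabitatBRT.from_dataframe(...).fit(config)`
returns a results object with the selected hyperparameters, the
cross-validated deviance surface, relative influence, marginal effects and
held-out AUC.

Hyperparameters — number of trees nt, learning rate lr, tree complexity tc —
are selected by a full grid search minimising 10-fold cross-validated
deviance with a bag fraction of 0.5. `BRTConfig.full_grid()` carries the
published grid (lr ∈ {0.1, 0.05, 0.01, 0.005, 0.001, 5·10⁻⁴},
nt ∈ {100, 600, …, 10000}, tc ∈ {1, 2, 3, 5, 7, 10}); staged evaluation
makes the nt dimension nearly free (one fit per (lr, tc, fold) at the
largest nt). CV folds are unstratified and seeded; a single-combination grid
skips the redundant CV pass. The tree backend is scikit-learn's
`GradientBoostingClassifier`; tc (splits per tree, gbm's interaction depth)
maps to `max_leaf_nodes = tc + 1` and the bag fraction to `subsample`.

**Relative influence** is the per-covariate share of total split
improvement, normalised to 100 %, averaged over five refits with different
bagging streams — influence from a single stochastic ensemble is noisy and
the replicate average is the stable estimate. **Marginal effects** are
partial-dependence curves on the logit scale over each covariate's observed
range, with 95 % confidence bands from bootstrap refits (default 50) at the
selected hyperparameters. **AUC** is the rank-based (Mann–Whitney)
statistic with ties counted half, verified against brute-force pair
counting.

## 7. The synthetic survey generator (`krillhab.simulate`)

The generator renders everything the real survey measured, with known ground
truth: a ship at 10 knots pinging once per second on a straight track
(configurable turn windows oscillate the heading channel for the heading
filter), TVG-shaped background noise with Gaussian dB jitter per frequency,
and elliptical aggregations with controlled Sv(120), dB difference, size
and depth, summed with the background in the linear domain. Planted
boundaries carry per-row half-width jitter whose amplitude varies between
swarms: real swarms range from smooth to convoluted, and this keeps
perimeter (hence roughness) from being a deterministic transform of height.

Swarm traits along the track are spatially autocorrelated (Gaussian-smoothed
latent fields; voyage preset correlation length 25 km) because the surveyed
prey field showed strong geographic stratification. Whales are placed near
krill swarms by a logistic link on z-scored log density, depth and height;
placed whales sit at a uniform bearing and 0.5–5 km range from the swarm, at
the passage time ± 30 min. Detections are then generated through the same
channels the ship had: visual sightings (daylight visual effort, range
≤ 12 km, recorded as ship position/heading/relative angle/range) and
sonobuoy bearing pairs (acoustic effort, buoys dropped along the track 10
and 40 minutes earlier, both within 40 km, recorded as exact great-circle
bearings). Effort is assigned in half-hour blocks against target fractions,
with visual effort only in daylight (solar altitude > 0 at the block
midpoint); night blocks spend the acoustic quota first, then the no-effort
quota, then degrade scheduled combined effort to acoustic-only.

Three presets define the study conditions:

* `SimConfig.voyage()` — 1728 planted krill swarms at 411 m spacing (40 of
  them inside heading-instability windows), ~7 % non-krill aggregations,
  effort fractions matching the observed 559/667/125/337 partition, and
  sparse whale aggregations (β₀ = −4.8, β_density = +2.0, β_depth = −2.0,
  β_height = +2.0) whose presence fractions at the three scales fall in the
  observed one-third to three-quarters range.
* `SimConfig.recovery()` — 1000 strong swarms (Sv −66…−46 dB, ≥ 4 dB above
  the delineation threshold; no planted overlap) with 18 km trait
  correlation, continuous effort, and a strong placement link
  (β₀ = −3.0, ±2.2): whales occur only in the best patches, as observed at
  sea.
* `SimConfig.recovery(null=True)` — zero placement coefficients, a rare
  (~1 %) uniform placement rate, and spatially *unstructured* traits, so
  that the covariates carry no information about the labels at all (see
  §8).

What the generator does **not** emulate: beam-pattern and multiple
scattering physics, whale movement between placement and detection,
transient/attenuated-ping noise, 3-D swarm structure, bottom echoes, and
krill length variation between swarms (a single survey-wide length feeds
the TS model). Passing recovery tests therefore demonstrate that the chain
of estimators is faithful under these idealisations, not that the ecological
conclusions transfer to any particular ocean.

## 8. Validation experiments and their interpretation

The **recovery experiment** (20 seeds × 1000 swarms) runs the full chain and
asks whether held-out AUC is high (≥ 0.8), whether the three planted drivers
occupy three of the top four relative-influence ranks, and whether the
marginal-effect directions match the planted signs. Replicate fits use a
fixed hyperparameter point (nt = 200, lr = 0.05, tc = 3); the 1000-swarm,
20-seed design makes a per-replicate grid search uninformative for what the
experiment measures, and the grid-search path is exercised separately.

The **null experiment** uses zero placement coefficients. An important
subtlety, discovered while validating: with spatially autocorrelated traits,
a random 75/25 split leaks location — test swarms sit inside the same whale
patches as their training neighbours and share nearly identical trait
signatures, so the model attains high AUC by patch memorisation even with no
trait–whale link at all. The null preset therefore removes the spatial
structure from the traits, which restores the intended reading
(AUC ≈ 0.5). The same leakage mechanism operates in any random-split
evaluation of spatially structured survey data, including the recovery
experiment here (part of its AUC is spatial interpolation rather than
transferable trait effects) and real analyses of this design; block or
leave-patch-out validation would be required to separate the two, and is
deliberately out of scope.

Numerical/degenerate-input conventions, in brief: no-data sentinel −999 dB
throughout; MVBS over a region uses valid samples only, and a region fully
masked at one frequency cannot be classified; a single-swarm table gets
NaN nearest-neighbour fields with a warning; zero-height swarms get a zero
backscattering coefficient with a warning; constant covariates remove no
outliers and take zero influence; AUC and the split require both classes.

## 9. Problem sizes

Default test and validation runs use: voyage preset 1728 swarms
(~138k pings × 125 depth bins), recovery/null presets 1000 swarms
(~61k pings), 20 seeds per experiment, influence averaged over 5 refits,
bootstrap bands over 50 refits (reduced in tests). These sizes keep a full
validation pass — both replicated experiments plus the voyage-scale survey —
under ten minutes on one core while the replicate rates remain stable enough
to interpret (a single seed batch of 20 resolves the recovery rate to ±5
percentage points).
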