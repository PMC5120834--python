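# Methods notes

This note documents the modelling choices behind `ensdm`: what the
synthetic landscape emulates, how the statistical pipeline is specified,
which defaults matter, and what the package's passing tests do and do
not demonstrate about real data.

## The synthetic archipelago

The generator is designed to reproduce the *statistical structure* that
an ensemble-SDM climate-vulnerability analysis of a small, climatically
graded archipelago assumes, not any particular geography.

**DEM.** Relief is Gaussian-smoothed seeded white noise plus a radial
island envelope, thresholded at a quantile so a target land fraction
(default 0.45) survives inside a forced one-cell sea margin. Sea is
nodata on every layer; all areal statistics count land cells only.
Default cell size is 100 m (the fine "topographic" resolution); the
default relief amplitude is 500 m above the coastline.

**Topographic covariates** (from the DEM):

- *slope* — central-difference gradient, degrees;
- *westerly aspect* — cosine of the angle between the downslope
  direction and due west, in [−1, 1] (prevailing-wind exposure), 0 on
  flat ground;
- *distance to coast* — Euclidean distance-transform cell distance to
  the nearest sea cell minus one, so coastal land (including single-cell
  islets) reads 0; off-grid counts as sea;
- *topographic wetness index* — ln(a / tan β) with a the D8 upslope
  contributing area per unit contour width and β the slope; tan β is
  floored at 10⁻³ to keep flats finite;
- *solar index* — clear-sky noon insolation on the inclined surface at
  one scalar latitude (default −51.7°, a small-archipelago
  approximation), normalised so flat ground = 1. Horizon shading is not
  modelled.

**Climate.** A 12-month temperature/precipitation cycle is built per
cell: annual-mean temperature = configured island mean (default 6.6 °C)
plus a lapse of 0.0065 °C m⁻¹, an east–west gradient (default 2 °C
across the grid, west warmer), and smoothed noise (sd 0.3 °C); annual
precipitation analogous (default island mean 559 mm, wetter west). All
anomaly terms are centred over land so the configured island means hold
exactly. The 19 bioclim summaries are computed from the monthly cycle,
which makes the identities BIO7 = BIO5 − BIO6, BIO10 ≥ BIO11,
BIO16 ≥ BIO17 and precipitation ≥ 0 true by construction. Five layers
(BIO2, BIO3, BIO8, BIO9, BIO15) are emitted but flagged excluded from
variable selection, mirroring surfaces that carry interpolation
artefacts in practice.

**Scenarios.** Warming is a pure translation of the temperature-*level*
layers (BIO1, BIO5, BIO6, BIO8–BIO11); diurnal range, seasonality and
precipitation are copied bit-identically, consistent with projections of
rising means but unchanged range and rainfall. Defaults: periods
2020/2050/2080 at +0.6/+1.2/+1.8 °C, five pseudo-RCMs whose long-term
spread is Gaussian with sd 0.34 °C (scaled proportionally for nearer
periods so warming is monotone within each RCM). The per-RCM jitter sd
is a parameter because the true model-to-model spread per period is not
something the generator should assert.

**Species.** Occurrence probability is a base rate (default 0.9) times a
product of per-covariate responses (Gaussian optimum/breadth or logistic
slope/midpoint). Sampling is rejection sampling over land cells against
probability × a clustered survey-effort field (smoothed hotspots,
default strength 0.6), so accepted points are distributed proportionally
to that product; points get continuous coordinates within their cell.
The two default species are narrow thermal specialists — a cold-adapted
"upland" species (BIO10 optimum 8.6 °C, breadth 0.45 °C, wetter sites)
and a warm-adapted coastal "western" species (BIO11 optimum 4.8 °C,
breadth 0.5 °C, near-coast) — because the analysis is designed for
range-restricted species whose distribution tracks temperature; broad
generalists would neither pass the TSS gate nor be sensible subjects for
this workflow. Default sample size is 60 records per species before
thinning.

**Protected areas.** Two blob-shaped networks ("NNR", "IPA") are cut
from smoothed noise fields at the quantile giving the requested land
coverage (defaults 5 % and 20 %); networks may overlap unless disjoint
masks are requested.

## The statistical pipeline

- **Thinning**: one uniformly chosen record per analysis cell
  (idempotent); species below 15 thinned records are skipped.
- **Pseudo-absences**: 10× presences, uniform without replacement over
  land cells not holding a presence, placed at cell centres.
  Pseudo-absence rows get weight n_presence/n_pseudo, so effective
  prevalence is 0.5 — a standard presence/background convention.
- **Collinearity screen**: pairs with |Pearson r| > 0.7 are processed in
  descending |r|; the member ranked lower in the configured ecological
  priority order is dropped. The retained set is guaranteed pairwise
  |r| ≤ 0.7. Zero-variance columns are excluded with a warning.
- **Stepwise AIC**: bidirectional from the intercept-only binomial GLM,
  capped at ⌊n_presences/10⌋ variables. The cap is applied to the
  presence count, not presences + pseudo-absences: the background is
  synthetic and 10× inflation would make a data-points rule vacuous.
  On perfect separation the step falls back to a ridge-penalised
  logistic fit with AIC computed from the unpenalised likelihood at the
  penalised coefficients (with a warning).
- **Splits**: ten stratified 80:20 train/test partitions. Stratification
  by label is a deliberate choice: at realistic presence counts an
  unstratified split can produce presence-free test folds.
- **Learners**: library-backed (scikit-learn, statsmodels) behind a
  uniform contract; the MaxEnt component is the penalised-logistic
  (maxnet-style) formulation on a linear + quadratic + pairwise-product
  basis, which avoids a Java dependency but is not the original MaxEnt
  implementation. Default hyperparameters are fixed in
  `learners.DEFAULT_SETTINGS` (GBM: 100 trees, lr 0.1, depth 3; RF: 300
  trees, min leaf 2; GAM: df 5 cubic B-splines; MaxEnt: C = 1 lasso) and
  are never tuned per species. The GAM escalates its smoothness penalty
  (α = 0, 1, 100) if perfect separation breaks the unpenalised IRLS fit.
- **Scoring scale**: probabilities map to integers 0–1000 by
  round-half-up; "score ≥ threshold" counts as predicted present. The
  threshold search maximises sensitivity + specificity exhaustively over
  all 1001 integers using exact integer arithmetic (so ties resolve
  deterministically to the smallest threshold).
- **Gate and ensemble**: algorithms with mean replicate TSS strictly
  above 0.7 are retained; weights are proportional to raw mean TSS
  (the simplest monotone choice). Ensembling happens on the probability
  scale and is rescaled to 0–1000 once, avoiding double rounding. The
  conventional quality bands (excellent > 0.8, good 0.6–0.8) are
  reported but only the 0.7 gate has any effect.
- **Operating threshold**: found once on the full-data ensemble scores
  at presence vs pseudo-absence rows and reused unchanged for every
  future period — range change must come from the climate, not from a
  moving cut-off.
- **Variable importance**: shuffle one covariate column, re-predict,
  importance = 100 × (1 − Pearson r against the original predictions),
  averaged over shuffles and clamped to [0, 100]. Importances are
  per-variable and unnormalised.

## Vulnerability metrics

All metrics compare against the present-day map, per RCM, then mean ±
SE (sd/√n, n = number of RCMs — RCMs are treated as replicates, exactly
as the significance tests do):

- % change in suitable area = 100 × (future − present)/present cells;
- % overlap = 100 × (present ∧ future)/present cells (resilience
  in place);
- % change in mean suitability = 100 × mean(future)/mean(present) on the
  continuous maps — below 100 means decline. Because "decrease by X %"
  is a different convention, the complement 100 − ratio is emitted
  alongside under its own label (`pct_suitability_decrease`) to avoid
  conflating the two.
- persistence = % of known (thinned) presence points whose cell stays
  suitable;
- protected-area overlap = % of suitable cells inside a network mask;
- refugia = cells suitable in the final period in a majority of RCMs
  (the agreement rule is a package choice; union and intersection rules
  are also available).

The Wilcoxon rank-sum test between the first and last future periods is
exact: all C(n_a + n_b, n_a) rank assignments are enumerated (midranks
for ties) and the two-sided p is twice the smaller tail, capped at 1.
At 5 vs 5 the smallest attainable p is 2/252 ≈ 0.008, and one step from
complete separation gives 4/252 ≈ 0.016. Beyond 12 total observations
the normal approximation is used with a warning.

## Reproducibility and problem sizes

Every stochastic operation takes an explicit seed; the pipeline fans a
single master seed out to per-stage seeds via CRC32 of a stage tag
(`stage_seed`), so any stage can be rerun independently and two runs
with the same master seed produce byte-identical metric CSVs.

The bundled analyses use a 128×128 grid (≈ 7 000 land cells), two
species with 60 records each, ten 80:20 replicates, and 3 periods × 5
RCMs — sizes chosen so a complete run finishes in well under a minute on
one core while keeping every statistical feature of the full-scale
problem (small presence counts, 10× background, replicate-level
significance testing).

## What passing tests do and do not show

The synthetic landscape has smooth Gaussian spatial structure, exactly
known niches, unbiased (or simply clustered-biased) detection and
perfectly co-registered covariates. Passing the pipeline's recovery
tests therefore shows the machinery is correct and well calibrated under
its own assumptions; it does not demonstrate robustness to the things
real archipelago data add: spatially autocorrelated survey effort
correlated with climate, positional error in records, covariate
measurement artefacts, dispersal limitation, or biotic interactions.
Range-change projections are potential-niche arithmetic: no dispersal
constraint is modelled, so realised changes would differ.

## Known limitations

- Rasters are planar and label-only in CRS terms; no reprojection.
  Nearest-neighbour resampling is the only grid alignment (deliberate:
  interpolation would invent intermediate climates).
- The TIFF dialect stores grid geometry in the ImageDescription tag; it
  round-trips within this package but is not a GDAL-georeferenced
  GeoTIFF. The ESRI ASCII grid is the canonical interchange format.
- The GAM and MaxEnt components are equivalents, not re-implementations,
  of the classical R/Java tools; coefficient-level agreement with those
  tools is not expected, contract-level behaviour is.
- The exact rank-sum enumeration is O(C(n, k)) and capped at 12 total
  observations before switching to the normal approximation.
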