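# Methods

This note documents the models and procedures riskdex implements, the
choices made where the design was genuinely open, and what the synthetic
study system does and does not emulate.

## The risk model

Risk follows the current IPCC decomposition into vulnerability, exposure
and hazard. All three components are built from **tie-averaged ranks**
rather than raw values: each variable is ranked over the scored assemblage
(average ranks on ties, so the rank sum is always n(n+1)/2), oriented so
that the largest rank is the most at-risk species, summed within its
component, and the three component sums are added and divided by the
assemblage maximum. The resulting index lies in (0, 1] with the riskiest
species at exactly 1. Rank-based aggregation makes the index invariant to
monotone transformations of any input variable and immune to scale
differences between, say, percent area change and fires per pixel; its cost
is that scores are relative to the assemblage, not absolute — adding or
removing species changes everyone's index.

Variable orientation is configuration, not hard-coded semantics
(`risk_engine.DEFAULT_DIRECTIONS`). Defaults: percent PDA change and
percent NPA change are protective (a larger value is safer, so they are
negated before ranking); the LUCC-unsuitable fraction, temperature and
precipitation change, fire density and hurricane intensity are aggravating.
The composite is therefore monotone: worsening exactly one variable of one
species can never lower that species' normalized risk (a property the test
suite checks over randomized assemblages).

**Vulnerability.** Sensitivity ranks eight biological characteristics.
Categorical traits map to {−1, 0, +1} risk values through an explicit,
overridable table (`vulnerability.DEFAULT_TRAIT_RISK`); the published
expert-elicited scoring this stands in for is not available, so the
defaults encode the uncontroversial directions (declining populations,
endemism, feeding specialism, cue dependency, low dispersal ability and
island restriction are risk-positive; data-deficient IUCN status is
neutral). Ecoregion occupancy enters as a negated count: occupying fewer
ecoregions means less ecological plasticity. Per-trait ranks are summed and
the sums ranked again. Adaptive capacity (NPA) is the percent change in the
*share* of a species' suitable cells lying inside protected areas; the
share-based reading (rather than the absolute in-PA pixel count) keeps the
quantity comparable across species with very different range sizes.
Zero-baseline conventions: current share 0 with positive future share maps
to +100; both zero to 0; an empty PA mask yields 0 with a degeneracy flag.

**Exposure.** PDA change is the signed percent change in suitable pixel
counts between current and future binary maps; −100 marks total loss, and
total-loss species are excluded from ranking and reported separately
(their risk cannot be computed once the area term degenerates). The LUCC
overlay counts the fraction of remaining future PDA on unsuitable land
classes — under the precautionary principle (WP) rainfed agriculture,
cattle grassland and urban; without it (WoP) urban only. Urban is
unsuitable under both readings since the substantive contrast concerns
agricultural land. Class sets are configuration keys.

**Hazard.** Four variables measured over the future PDA under the active
dispersal assumption: PDA-mean absolute temperature change (°C), PDA-mean
absolute precipitation change (mm), fire count per PDA pixel, and hurricane
intensity, read as (mean category × frequency) averaged over the PDA —
equivalent to weighting each intensity level by the fraction of the PDA it
covers. Both a larger category and a more frequent regime increase the
product monotonically; the formula is configurable. The hazard score sums
all four variable ranks by default; a three-variable variant excluding
precipitation change is available (`include_p_change=False`) because the
two plausible readings of the aggregation differ on this point.

## The niche-modelling protocol

Occurrences pass through: exact-coordinate deduplication (6 decimal
places); greedy spatial thinning in input order at 10 km minimum haversine
separation (sphere radius 6371.0088 km), with an automatic 5-km retry from
the deduplicated records when a species would otherwise miss the floor (the
endemic relaxation — same operation, smaller distance); a 25-unique-record
inclusion floor; and, for record-rich species, distance-based subsampling
to m(n) = round(300 − 275·exp(−(n−25)/τ)), τ = 275/ln(300/275), which is 25
at n = 25 and saturates at 300. Subsampling repeatedly locates the closest
pair and removes the member whose second-nearest-neighbour distance is
smaller (ties break toward the lower input index), preferentially keeping
spread-out records; the retained minimum pairwise distance never decreases.
Greedy input-order thinning was chosen over randomized thinning for
reproducibility without a seed.

The calibration/transference area is buffer₂°((∪ occupied ecoregions) ∩
buffer₃°(records)), in decimal degrees. Records outside every ecoregion
contribute through the locality buffer alone, with a warning.

Variable pre-selection samples the stack at occurrence plus pseudo-absence
locations and iteratively drops the variable with the largest mean absolute
Pearson correlation to the others until every pair satisfies |r| < 0.8
(ties drop the later-ordered variable; constant variables are dropped with
a warning).

Three lightweight learner families stand in for the usual GLM/GAM/CTA/RF/
GBM/Maxent set — the bespoke content of the protocol is the evaluation and
ensembling machinery, not the off-the-shelf learners: a regularized
logistic regression on standardized linear + quadratic climate terms
(well-specified for Gaussian niches), a depth-limited classification tree,
and a rectilinear climate envelope scoring 1 inside the presence min–max
box and decaying exponentially with normalized exceedance outside. The
family list is config-extensible. Each of R = 10 replicates per family is
fitted on a fresh stratified 70/30 split (presence count rounded half-up)
of the presences and the 1000 shared pseudo-absences, drawn once per
species uniformly over the calibration area's cells. Validation metrics are
Kappa, TSS = sensitivity + specificity − 1, and AUC computed as the
Mann–Whitney rank statistic with ties counting one half.

Binarization maximizes TSS over the midpoints of sorted unique scores plus
{0, 1}, breaking ties toward the lowest threshold; scores equal to the
threshold count as presence. Replicate *binary* maps (not continuous
scores) are combined into an AUC-weighted mean, dropping replicates with
validation AUC ≤ 0.5 (chance); the ensemble surface is binarized by
max-TSS on the pooled validation data of the retained replicates, scored by
the ensemble itself. Whether threshold selection should use calibration or
validation data is not settled; validation data is used here. Ensembling
sorts replicates into a canonical order first so the floating-point sum is
independent of caller ordering.

Dispersal: limited full dispersal = any suitable cell within the
calibration/transference area (the maps are already restricted to it);
non-dispersal = cellwise AND of future with current suitability. The risk
index uses limited full dispersal; the non-dispersal variant is reported
for comparison.

## The synthetic study system

`synthetic_world` generates a complete desk-scale study: an 8° × 8°
landscape at 1/15° (~7.4 km) resolution — 120 × 120 cells; six climate
variables built from low-frequency sinusoids plus Gaussian-smoothed random
fields, with a temperature-like surface (latitudinal gradient, °C) and a
precipitation-like surface (mm, clipped at 0), each accompanied by an
engineered collinear partner (|r| ≈ 0.97) to exercise the 0.8 rule; a 3 × 3
block partition into ecoregions; a smooth-field protected-area mask
covering 12 % of cells (roughly the protected fraction of Mexico);
categorical LUCC maps in which urban is fixed and rainfed agriculture and
cattle grassland expand monotonically into natural vegetation by 35 % per
period step from initial fractions of 15 % and 10 %; Poisson fire counts on
a southwestern gradient; and hurricane category/frequency surfaces confined
to an eastern coastal band, decaying inland.

The default scenario design is the current climate plus two contrasting
2070 futures — one warmer and wetter (ΔT ≈ 3.5 °C, ΔP ≈ +12 mm), one
milder and drier (ΔT ≈ 2.0 °C, ΔP ≈ −45 mm) — inside the envelope of
published CMIP6 projections for Mexico; `full_scenario_design()` produces
the 2 GCM × 2 SSP × 3 period = 12-combination cross. Warming anomalies are
smooth fields clipped below at half the scenario mean, so no cell escapes
warming; with zero anomaly the future stack equals the current one exactly.

Species carry Gaussian niches over temperature and precipitation;
suitability exp(−½‖z‖²) ≥ 0.5 defines the true-suitable mask, and records
occur only in true-suitable cells, with density proportional to
suitability (occupancy requires minimally suitable conditions; the floor is
configurable). Record counts are log-uniform between 80 and 4000 per
species. Four archetypes fix the ground-truth response to warming:

- **stable** — precipitation-limited (thermal breadth 5 σ_T, rainfall
  breadth 0.35–0.5 σ_P): a rainfall band that warming barely moves
  (area change < 5 %) yet that is learnable against background;
- **shrinking** — a cool-side thermal band (0.45–0.75 σ_T at the 15–35 %
  temperature quantile) eroded by warming;
- **expanding** — optimum just beyond the current warm margin, wide enough
  to hold a foothold today; rainfall optimum anchored to the warm region so
  the niche is never empty;
- **doomed** — a cold-margin thermal band spanning
  [Tmin + 0.05 ΔTmin, Tmin + 0.95 ΔTmin], where ΔTmin is the smallest
  warming any future scenario applies anywhere: suitable today, and
  provably without a single suitable cell in every future. Doomed species
  receive ≥ 400 records so that the record floor, not sampling noise,
  decides whether they are modelled.

Niche optima cluster near the landscape median so that stacked ranges form
species-rich hotspot cells, as real assemblages do. Trait tables draw the
eight sensitivity characteristics and the order/trophic/body-size/
locomotion labels from fixed categorical distributions; ecoregion occupancy
is computed from the actual records. The island-restriction trait is a
boolean flag, not literal island geometry.

What the generator does **not** emulate: real geography or realistic
spatial covariance of climate; sampling bias and georeferencing error in
occurrence data; trait correlations within clades; LUCC transition dynamics
(maps are threshold expansions of a fixed propensity field); and any
dependence of hazards on the future period (fires and hurricanes are
observational, as in the protocol). Passing tests on this world therefore
demonstrate that the machinery is correct and that known structure is
recoverable — not that the index is well-calibrated for any real fauna.

## Numerical and interface choices

- **Grids.** One shared north-up, cell-centre-registered WGS84 grid; all
  area quantities are pixel counts; mixing grids anywhere raises. Rasters
  are read and written as ESRI ASCII grids (plain text) with a `.prj`
  sidecar naming the CRS; reads validate CRS and, on request, grid
  geometry. Polygons travel as GeoJSON, tables as CSV with declared
  columns and enum validation that names the offending row.
- **Richness threshold.** Assemblages of ≥ 100 species use the absolute
  cut of 75 species. For desk-scale assemblages the default is 75 % of the
  observed maximum richness — three-quarters of an entire assemblage never
  co-occurs in one cell, so a fraction of the richness peak is the reading
  that still delimits non-empty rich areas; 75 % of n remains available.
- **Top decile.** ⌈n/10⌉ species per scenario × principle; ties at the cut
  are all included (with a warning); assemblages under 10 species flag one.
- **Group percentages** round half-up to two decimals. Wilcoxon rank-sum
  comparisons use the exact null distribution when the smaller group has
  ≤ 8 members and the pooled values are tie-free, an exhaustive/seeded
  permutation scheme when ties make the exact distribution invalid, and the
  tie-corrected normal approximation otherwise. No multiple-testing
  correction is applied across group comparisons.
- **Determinism.** Every stochastic step draws from a generator derived
  from the world seed via `SeedSequence` spawning; rerunning a
  configuration reproduces every output byte-for-byte. The pipeline writes
  a manifest with the config hash and seed.

## Problem sizes

Default runs model 20 species on the 120 × 120 grid with 10 replicates ×
3 families and 1000 pseudo-absences (≈ 10 s on one CPU). The test suite
uses smaller worlds (80 × 80, 4–12 species, 2–3 replicates) and, for
ground-truth recovery, record-rich worlds of four species with 10,000 raw
records each, modelled at full replication; these sizes were chosen so the
full suite exercises every stage at meaningful sample sizes while staying
interactive.

## Known limitations

- Scores are assemblage-relative ranks: they support prioritization within
  the evaluated set, not absolute risk statements or cross-study
  comparison.
- Pseudo-absences are contaminated by definition (some fall on truly
  suitable cells), which biases max-TSS thresholds for very widespread
  species; the effect shrinks as species prevalence within the calibration
  area falls.
- The exponential subsampling curve is anchored only at its two published
  endpoints; the original curve's shape between them is unknown, and the
  implementation makes it configurable.
- Buffers are taken in decimal degrees (as specified), so calibration
  areas are wider in kilometres near the equator edge of a landscape than
  at its poleward edge.
- With fewer than ~10 scored species the decile machinery degenerates to
  flagging a single species.
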