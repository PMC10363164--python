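# Methods

This note documents the models, rules and numerical choices implemented in
`plantedmap`, and what the synthetic landscape does and does not emulate.

## The mapping problem

The target quantity is a per-cell (0.009° × 0.009°, ~1 km²) probability
that a forest cell is planted rather than naturally regenerated, derived
from evidence layers of very different reliability: ground observations,
field-verified national vegetation/forest-cover maps, and wide-area
planted-extent products inferred from satellite data. Because no single
labelling of such evidence is defensible, the pipeline trains three
parallel models on label sets of graded strictness and reports their mean
with the liberal/conservative members as an uncertainty envelope.

## Label fusion (QODI)

Sources split into *in-situ grade* — ground plots aggregated to cells by
strict majority vote (exact ties carry no evidence), plus two national
maps rooted in field observation — and *map grade* — three planted-extent
products that only ever assert "planted" or stay silent. With `I` = any
in-situ-grade planted flag and `k` = count of map-grade planted flags:

* lower: planted iff `I or k = 3`; grey (excluded) iff `not I and k ∈ {1,2}`
* mid:   planted iff `I or k ≥ 2`; grey iff `not I and k = 1`
* upper: planted iff `I or k ≥ 1`; no grey area

All remaining cells are **natural** — absence of planted evidence is
treated as a natural label, not as missing data. Grey cells are removed
from their level's training set only; they are still mapped at prediction
time. Two fusion decisions were genuinely open and are fixed here as
package policy: (i) an in-situ *natural* reading does not veto map-grade
planted flags (the upper rule is a pure union; at mid/lower a cell with
in-situ natural and one map-grade flag follows the grey rules with
`I = 0`); (ii) the forest mask (tree height ≥ 5 m, the FAO forest floor)
is boundary-inclusive and treats missing height as non-forest.

Biome strata: seven raw ecoregion classes collapse to Temperate
Grassland / Temperate Forest / Tropical Forest and Savanna; the two
temperate strata merge at mid and lower, where the grassland stratum is
too thin to train separately.

## Predictor completion

The 57-slot predictor vector is completed before training and prediction.
The four lidar-structure slots are filled by regression forests on the
seven optical vegetation indices: a single fit on all complete rows for
the upper level; for mid and lower, the mean of 10 forests refit on
bootstrap subsamples of min(200,000, n) rows. Cross-validation repeats
the same sampling (training rows drawn with replacement — 90% of n for
upper — with the never-drawn rows as the test set) and reports RMSE and
out-of-sample R² = 1 − SSE/SST (the out-of-sample definition is a package
choice) with bootstrap-t 95% intervals. All other predictors take the
per-column median of observed values — deterministic, order-independent,
and sufficient for slots that are nearly complete; a wholly missing
column is an error, not a silent zero.

Imputation forests are deliberately small: 25 trees, `min_samples_leaf 5`,
all features per split, each tree on a 25% bootstrap. The response being
recovered is smooth in seven predictors, and on held-out data these
settings are statistically indistinguishable from full-depth,
full-bootstrap forests at several times the cost.

## Bound ensembles

Per level and biome stratum, 20 random-forest members; each member's
training sample undersamples the majority class to the minority count so
classes are exactly balanced. Tree counts are 100 (upper, mid) and 200
(lower); predictors-per-split are 7 (the `floor(sqrt(57))` library
default) for upper, 26/42 (temperate/tropical) for mid and 20/40 for
lower. Percent planted is the fraction of all trees across members voting
planted — members have equal tree counts, so this equals the mean of
per-member vote fractions. The final value is the unweighted mean of the
three bounds, thresholded at ≥ 0.5 (boundary planted) for the map; the
mean is *not* clamped to the [lower, upper] interval, because the bounds
are different models rather than order statistics and can cross. Inside
each member, trees grow on 25% bootstrap draws of the member sample
(`max_samples 0.25`) — a fit-cost choice measured to leave vote accuracy
unchanged on this landscape. Cells in countries with an authoritative
national planted-forest map take the map's label directly (source
`national_map`), with percent fields set missing.

The candidate-comparison harness (random forest vs. RBF support-vector
machine vs. gradient-boosted trees, all at library defaults, scored over
10 balanced bootstrap splits with t-based intervals) and the
hyperparameter tuner (smallest grid value whose mean accuracy *and* F1 sit
within 0.002 of the grid maxima, ties to the cheaper value; the two
dimensions tuned sequentially, trees first) are provided as reproducible
machinery around those defaults. Whether held-out sets should be
class-balanced is ambiguous for heavily imbalanced data, so the harness
reports both as-is and balanced test metrics.

## Dominant genus

Importance value per species in a plot: percent basal area + percent stem
count (sums to 200). Plots with zero total basal area fall back to
doubled stem shares, flagged in the log. The plot dominant is the IV
argmax, ties broken by larger basal-area share then lexicographic species
name (logged). Cell labels are the majority genus among plot dominants
inside the predicted planted extent; tied cells are excluded — mirroring
the 50/50 removal rule used for in-situ points — and genera with fewer
than 60 labelled cells are dropped after aggregation. Class balancing
equalises every genus at the rounded mean of the original counts
(undersampling without replacement above, oversampling with replacement
below); the mean is the symmetric choice between the minority and
majority conventions and is configurable. The classifier is a
default-setting random forest on 52 predictors (the stack minus roadless
area and the four lidar slots), assessed by 100 iterations of stratified
90/10 splits with balancing applied to the 90% only.

## Validation metrics

Confusion elements are proportions of evaluated cells with positive =
planted; accuracy = tp + tn, precision, recall and F1 follow, with
undefined denominators returned as NaN (never 0) so degenerate cases fail
loudly. Intervals are bootstrap-t: mean ± t(0.975, n−1)·sd/√n. Reports
are printed at 3 decimals; raw values are kept in machine output.

## Synthetic landscape

The generator emulates the statistical structure the pipeline assumes:

* **Truth** — Gaussian white noise smoothed at `autocorr_length` cells and
  quantile-thresholded to the target planted fraction (default 0.30, a
  realistic regional share of planted forest within forest area).
* **Sources** — each source observes truth independently through
  (sensitivity, specificity, coverage), defaults 0.9/0.95 with partial
  coverage; planted-only products stay silent on natural cells. Country
  bands (4 longitudinal strips) give the national maps their domains and
  exercise the override path. Errors are independent across sources given
  truth — the real spatial correlation of source errors is unknown, and
  this is the documented simplification.
* **Predictors** — unit-variance Gaussians with class-mean shifts (default
  1 SD on the seven optical and seven leading bioclimate slots, 0.5 SD on
  human footprint); lidar slots are linear mixtures of the optical slots
  at a 50% signal share with MCAR gaps (default 30%, inside the 22–44%
  range seen per label grade in real lidar sampling); topography and soil
  are class-neutral but carry genus-specific mean offsets (SD 1) so the
  genus classifier has signal orthogonal to the planted/natural problem.
* **Heights** — class-specific lognormals with a configurable share of
  sub-5 m cells to exercise the forest mask.
* **Plots** — placed in forest cells; 1–8 species with Dirichlet
  basal-area shares and Poisson stem counts; the leading species carries
  the cell's latent genus region with probability 0.85.

What passing tests on this landscape show: the rule sets, resampling
protocols and estimators are implemented correctly and recover known
structure at realistic noise levels. What they do not show: performance
on real remote-sensing data, whose predictor distributions are
non-Gaussian, whose source errors are spatially correlated, and whose
label imbalance is far stronger.

## Problem sizes and determinism

The study-scale configuration is 200×200 cells (~36,000 forest cells,
~140 member-forest fits); the acceptance script and the end-to-end test
both use it and run in minutes on one core. Examples use 40–80-cell grids
with trimmed member counts, stated in each script. One master seed feeds
a single generator from which every stage draws sub-seeds in a fixed
order, so all artifacts — including CSV and raster bytes — reproduce
exactly for a fixed seed.

## Known limitations

* No spatial cross-validation; splits are random over cells, so spatial
  autocorrelation inflates apparent skill exactly as it would with naive
  splits on real data.
* The general imputer is a median fill; no multivariate or spatial
  gap-filling for the non-lidar slots.
* Areas use a spherical Earth (authalic radius; < 0.3% error at the
  latitudes of interest), and vector/raster output is GeoJSON/ASCII grid.
* No probability calibration of the percent-planted values, and no
  monoculture-vs-mixed discrimination in the genus map.
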