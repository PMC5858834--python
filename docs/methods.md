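# Methods

## Model overview

The pipeline treats the climatic niche of an ecosystem stable state as a
proxy for its resilience. Ensemble suitability models fit on mutually
exclusive presence–absence data give each pixel a consensus suitability in
[0, 1]; rescaled to integers on 0–1000 this is the resilience metric
(capacity to recover after disturbance, maximal at the niche optimum), and
its linear inversion, stress = (1000 − resilience)/10 on a 0–100 axis, is
the climate-stress gradient. Sensitivity, exposure, and adaptive capacity
are then quantified per ecosystem, and together rank vulnerability to
climate change.

### Stable-state classification

Tree cover partitions into grassland [0, 5], savanna (5, 60], forest
(60, 100]. The forest bound is strict — cover exactly 60 is savanna —
because forest is defined as *above* 60%. The 5-boundary is ambiguous in
the usual verbal statement of the bands ("zero to 5", "5 to 60"); we close
grassland on the left, `[0, 5]`, and make both thresholds configurable.
The consensus repair rule is one-directional: a pixel classified below the
forest threshold but labeled forest by an independent land-cover census is
upgraded to forest; nothing is ever downgraded. The rule is idempotent.
Block-majority resampling takes the modal state per block (missing pixels
excluded, all-missing blocks stay missing); ties break toward the fixed
order grassland < savanna < forest, the same order used everywhere a tie
must be resolved. Trailing partial blocks vote with their available
pixels. A mean-then-threshold alternative was considered and rejected: the
mode never invents a state absent from the block, which the mean can.

### Occurrence tables

Points are sampled uniformly without replacement from valid pixels —
the spatial sampling scheme behind published point sets of this kind is
rarely stated, and uniform sampling is the assumption-free default.
Coordinates are pixel centers under a half-open pixel model (the transform
origin is the outer corner of pixel (0,0)). Presence flags are one-hot:
the stable states are geographic substitutes, so recording one present
marks the others absent.

### Niche models

Four methods are implemented natively behind a registry
(`register_method` is the plug-in point; fitted models only need a
`predict` in [0, 1]):

* **envelope** — per-predictor bounds at the [q, 1−q] empirical quantiles
  of presence values (default trim q = 0.025, the conventional
  surface-range-envelope default); predict is the indicator of lying
  inside all bounds.
* **logistic_glm** — maximum-likelihood logistic regression via IRLS on
  predictors standardized to zero mean / unit variance (training
  statistics reused verbatim at projection time), polynomial degree 1 or 2
  (default 2, no interactions; curvilinear responses are standard ensemble
  practice). Convergence: max |Δβ| < 1e−8, at most 100 iterations.
  Complete separation or divergence triggers one ridge-stabilized restart
  (penalty 1e−4·n), flagged in `training_summary.ridge_fallback`. The
  observed-information covariance is stored; for degree-1 fits,
  `logistic_coefficients_original_scale` maps coefficients and standard
  errors back to the raw predictor scale.
* **discriminant** — two-class linear discriminant; the pooled within-class
  covariance is shrunk toward its diagonal, S_reg = (1−reg)·S + reg·diag(S)
  (default reg 0.05), and prediction is the Gaussian posterior of presence
  with empirical priors. reg = 0 with a singular covariance raises with a
  suggestion to increase it.
* **tree** — greedy binary partitioning minimizing Gini impurity
  (default max depth 6, min leaf 10); leaves predict their presence
  fraction. Among equal-gain splits the lowest predictor index and then
  the lowest threshold wins, making fits bit-reproducible.

Variable importance is permutation-based: 1 − Pearson correlation between
predictions on the original table and on a table with one predictor
permuted, averaged over shuffles and clipped to [0, 1] — the established
convention in the ensemble-modeling literature. A model that provably
ignores a predictor scores exactly 0 (identical predictions give
correlation 1 regardless of variance). Constant original predictions are
flagged and give all-zero importances; a constant permuted vector with
varying originals counts as correlation 0.

Fitted models serialize to a versioned JSON document (method, hyperparams,
parameters, standardization constants) and rebuild with a working
`predict`.

### Evaluation and consensus

Splits are stratified by the presence flag (protecting the rare grassland
class) with the train size exactly round(0.75·n) and per-class counts
within one row of proportionality; defaults are 10 replicates at 75/25.
TSS binarizes scores at a cutoff (score ≥ t → presence); because
suitabilities are continuous, each member is scored at its TSS-maximizing
cutoff, found by an exact scan over midpoints of adjacent sorted unique
scores plus {0, 1} (smallest maximizer on ties; tested against dense-grid
brute force). ROC AUC is the rank-based Mann–Whitney estimator with ties
counting ½. Members with test TSS ≥ 0.7 are retained, refit on the full
table (a flag preserves split-fit projection instead — refitting uses all
information for the map while keeping the evaluation honest), projected,
and averaged pixel-wise; the ensemble averages across methods *and*
replicates that pass. An empty ensemble raises an explicit error carrying
the full evaluation table rather than silently averaging nothing.

### Resistance curves

Resilience = round(consensus × 1000), rounding halves up. Stress response:
presences of an ecosystem are binned along stress into 20 equal-width bins
on [0, 100] (bin count configurable) as relative frequencies in %. The
resistance model is fit as y = a·e^(bx) by Levenberg–Marquardt least
squares, initialized from the ordinary regression of log(y + 1e−3) on x
(the offset keeps empty bins finite), tolerances 1e−12, at most 2000
function evaluations. The model is sometimes written y = a·b^x; a decay
base cannot be negative, and with the e^(bx) parameterization the reported
negative b values are decay rates per stress unit — this reading is the
only one consistent with negative printed coefficients. Ecosystems are
ranked by |b| descending (largest |b| = least resistant); exact ties share
a rank and are flagged.

### Climate space

Presences are binned on a 2-D climate plane (default 50×50 bins; moisture
ACP×PSC and energy AAT×ART are the canonical planes, any predictor pair is
allowed), each bin carrying occupancy and mean resilience sampled at the
presence pixels. The non-analog polygon — the direction observed and
simulated climate trends point — is supplied by the user in predictor
units; the shipped default is only an editable example covering the
arid/seasonal (moisture plane) or hot/wide-range (energy plane) quarter.
`exposure_fraction` is the fraction of bin weight (occupancy or
occupancy × resilience) whose bin centers the polygon covers; centers on
the edge count as inside. It is monotone under polygon growth.

In `compare_vulnerability` the exposure *axis* is non-analog exposure =
1 − overlap: an ecosystem whose occupied climate space barely overlaps
where the climate is heading will be left outside its niche, which is what
exposure to non-analog conditions means; ecosystems overlapping the trend
polygon are favored by the change, not threatened. Adaptive capacity is
niche breadth: the per-axis span of bin centers (and the count of bins,
an area proxy) keeping occupancy > 0 and mean resilience at or above a
threshold (default 500 of 1000); it is monotone non-increasing in the
threshold. Each axis is ranked (1 = most vulnerable: highest |b|, highest
non-analog exposure, lowest breadth) and the vulnerability score is the
mean rank; this is a deliberately qualitative operationalization of an
assessment that is usually made visually, and is labeled as such.

## Synthetic landscape

The generator emulates the structure of a continental tree-cover /
bioclimate dataset:

* **Climate fields** — low-pass-filtered Gaussian noise plus a latitudinal
  trend, min–max rescaled into physical ranges: ACP 50–6200 mm·yr⁻¹
  (arid deserts to very wet equatorial zones), PSC 5–150%, AAT −5–30 °C
  (high-altitude frost to equatorial lowlands), ART 1–18 °C. Trend signs
  are fixed per predictor (ACP+, AAT+ equatorward; PSC−, ART−) so every
  landscape has a wet/hot/aseasonal end and an arid/seasonal/cold end.
  A `trend_shape` bend can pile many rows onto a near-extreme plateau
  (a rainforest-core analog). Smoothing radius 8 px gives lag-1
  autocorrelation comparable to real climate grids.
* **Occupancy** — per-ecosystem separable Gaussian niches
  exp(−((v−opt)/tol)²) multiplied across predictors (the simplest form
  consistent with a unimodal climatic optimum; the pipeline never assumes
  it when fitting). Default mode assigns the argmax state (ties to the
  fixed state order); `occupancy_mode="sample"` draws the state with
  probability proportional to suitability, producing the smooth decline of
  occupancy away from the optimum that graded frequency-versus-stress
  responses require. A `state_noise` fraction of pixels is re-assigned
  uniformly (default 2%, emulating classification error).
* **Tree cover** — per-state beta draws rescaled into the state's band
  (shapes 2,5 / 2.5,2.5 / 5,2 put one interior mode in each band);
  savanna and forest samples are clipped strictly above their open lower
  edges so re-classification recovers the generating states exactly.
* **Corruption** — exactly round(f·n_forest) forest pixels, drawn without
  replacement, get cover redrawn uniformly in [10, 59] — unambiguously in
  the savanna band, the land-use failure mode the consensus rule repairs —
  while the returned consensus grid keeps the pre-corruption states.

Default niche optima follow the study system's descriptions: forest wet /
aseasonal / hot with narrow tolerances, savanna intermediate and broad,
grassland arid / seasonal / cold-tolerant and widest in temperature.

What the generator does *not* emulate: real geography (coastlines,
mountain ranges, spatially correlated predictor interactions), observation
error in the predictors, spatial autocorrelation of the sampling scheme,
and disturbance dynamics (fire, land use as a process). Passing tests
therefore show the pipeline's operations are correct and the qualitative
mechanisms reproduce under controlled conditions — not that the numerical
coefficients transfer to any real landscape.

### The forest-concentration scenario

`forest_concentration_config()` is a constructed landscape embodying the
mechanism that makes forests the most climate-sensitive state: a large
homogeneous wet plateau owned by forest (most forest presences at
near-zero stress), grassland anchored at the arid/seasonal end, and
savanna as the transitional state occupied probabilistically across its
whole suitability gradient (presences spread evenly along stress). The
geometry — niche positions and tolerances expressed as fractions of the
latitudinal gradient, differentiated along the moisture axis with very
broad temperature tolerances — was designed against two analytic
requirements computed directly from the generating model: each state's
Bayes-limit TSS must clear the 0.7 ensemble filter with slack for model
error, and the fraction of presence mass at posterior ≥ 0.95 must order
forest > grassland ≥ savanna. On such landscapes the fitted decay rates
order |b_forest| > |b_grassland| ≥ |b_savanna| and the vulnerability
ranking places forest first. The scenario is meaningful only while all
three states keep a viable share of the landscape; grassland's dry anchor
zone is the noise-sensitive part, and realizations where its share
collapses below ~12% degenerate its response curve.

## Numerical choices and degenerate inputs

* All randomness flows from explicit integer seeds; the pipeline derives
  per-stage seeds from the run seed by hashing, so stages are individually
  reproducible and independent of each other.
* Problem sizes used in the shipped tests and acceptance script — 200×200
  landscapes, 2500–4000 occurrence points, 10 replicates — are the
  package's default study scale; they give stable ensemble statistics
  while keeping any run in the seconds-to-minutes range.
* Suitability predictions are clipped to [0, 1] after each method's raw
  output; logistic and discriminant linear predictors are clamped at ±35
  before the inverse logit to avoid overflow.
* `best_tss` on all-equal scores returns threshold 0 with TSS 0.
* Empty bins enter the exponential fit as zeros (they are informative);
  an all-zero response or fewer than 3 non-empty bins is an error.
* Rasters are written as single-band TIFFs carrying the standard GeoTIFF
  tags (ModelPixelScale, ModelTiepoint, GDAL nodata) plus a JSON
  ImageDescription with the CRS label; integer grids round-trip
  bit-exactly, float32 to 32-bit precision. States are uint8 (nodata 255),
  resilience uint16 (nodata 65535).

## Known limitations

* Only four of the many published suitability methods are implemented;
  the registry accepts user methods, but no claim of numerical
  equivalence with any existing ensemble platform is made, including for
  variable importance (the 0–1 permutation convention is one of several).
* The exposure and adaptive-capacity metrics are numerical stand-ins for
  an assessment usually made by inspecting climate-space figures; their
  absolute values depend on binning and polygon choice, and only
  comparisons across ecosystems under identical settings are meaningful.
* The resistance coefficient b depends on the calibration of the consensus
  suitability (a prevalence-dependent quantity), so b values are
  comparable across ecosystems within one run, not across datasets.
* With block-majority resampling, the output transform scales the pixel
  size; no reprojection between coordinate systems is implemented.
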