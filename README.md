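# nicheresilience

Measuring the resilience of terrestrial-ecosystem stable states from their
climatic niche.

Tropical and subtropical landscapes settle into three alternative stable
states of tree cover — grassland (0–5%), savanna (5–60%), and forest
(>60%) — visible as the three modes of the tree-cover frequency
distribution. This package implements a pipeline that turns that
observation into a quantitative vulnerability assessment:

1. **Stable-state classification** — tree-cover rasters are partitioned
   into the three bands, optionally repaired against an independent
   consensus land-cover product (pixels the satellite product degrades
   below the forest threshold but the census labels forest are upgraded
   back), coarsened by block-majority resampling, and converted into
   mutually exclusive presence–absence point tables.
2. **Ensemble niche modeling** — four natively implemented suitability
   methods (surface-range envelope, logistic GLM, linear discriminant,
   classification tree) map the four bioclimatic predictors — annual
   cumulative precipitation (ACP, mm·yr⁻¹), precipitation seasonality
   coefficient (PSC, %), average annual temperature (AAT, °C), and annual
   range of temperature (ART, °C) — to suitability in [0, 1]. Each
   (method, replicate) member is evaluated on held-out data over 10
   stratified 75/25 splits with the True Skill Statistic
   (TSS = sensitivity + specificity − 1) and ROC AUC; members with test
   TSS ≥ 0.7 enter the arithmetic-mean consensus.
3. **Resilience and climate stress** — consensus suitability is read as
   resilience, rescaled to integers on 0–1000 (capacity to recover after
   disturbance, maximal at the niche optimum), and inverted into a climate
   stress gradient on 0–100. For each ecosystem the relative frequency *y*
   (%) of its presences is binned along stress *x* and fit with the
   exponential resistance model *y = a·e^(bx)*; the decay rate *b* (per
   stress unit, negative) indexes resistance — ecosystems whose
   observations collapse quickly under stress have large |b| and low
   resistance.
4. **Climate-space vulnerability** — resilience is projected into 2-D
   climate planes (moisture ACP×PSC, energy AAT×ART); against a polygon
   marking where the climate is heading (drier, more seasonal, hotter),
   the pipeline computes non-analog exposure (1 − overlap of the occupied
   space with the polygon) and adaptive capacity (the span of climate
   conditions holding resilience above a threshold), then combines
   sensitivity |b|, exposure, and capacity into a vulnerability ranking.

A synthetic landscape generator drives the whole pipeline without any
external data: smooth climate fields in realistic physical ranges,
climate-conditioned stable-state occupancy (deterministic argmax or
probability-proportional sampling), trimodal tree cover, and land-use
corruption with a consensus grid that remembers the truth.

## Worked example

```python
import nicheresilience as nr

cfg = nr.RunConfig(outdir="run", seed=1, n_points=4000)
cfg.synthetic = nr.forest_concentration_config()   # forest-concentration scenario
out = nr.run_pipeline(cfg)

import json
summary = json.loads((out / "summary.json").read_text())
print(summary["class_shares"])
print(summary["resistance_b"])
print(summary["most_vulnerable"])
```

prints (values computed by this run):

```
{'forest': 0.501, 'grassland': 0.176, 'savanna': 0.323}
{'forest': -0.2956, 'grassland': -0.0597, 'savanna': -0.0291}
forest
```

Half the landscape is the wet forest plateau, yet the forest stress
response decays an order of magnitude faster than the savanna one
(|b| 0.296 vs 0.029): forest presences pile up at the lowest climate
stress, so a small stress increment removes a large share of them, while
savanna — occupied probabilistically across its whole suitability
gradient — barely responds. Grassland sits in between. Combined with
forest's low overlap with the direction of climate change and its narrow
high-resilience niche, the vulnerability ranking places **forest** first.

The run directory also holds the per-ecosystem evaluation tables
(`evaluation_*.csv`), resilience rasters (`resilience_*.tif`, uint16
0–1000), stress-response curves and fits (`stress_response_*.csv`,
`stress_fit_*.json`), climate-space surfaces, the vulnerability table, and
a `manifest.json` with a content hash of every artifact.

The same stages are exposed on the command line:

```
nicheresilience simulate --outdir sim --seed 3
nicheresilience classify sim/tree_cover.tif --consensus sim/consensus_states.tif --out states.tif
nicheresilience occurrences --states states.tif --climate-dir sim --n-points 2500 --seed 4 --out occ.csv
nicheresilience ensemble --occurrences occ.csv --climate-dir sim --ecosystem savanna --outdir ens
nicheresilience run --outdir fullrun --seed 6
```

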