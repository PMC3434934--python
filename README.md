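# anurainvade

Why do some introduced frogs and toads establish breeding populations while
others vanish?  This package implements, as a tested and reusable pipeline,
a comparative analysis of establishment success in anuran introductions:
climate matching between the native range and the introduction region,
introduction pathway, geography and life-history traits are weighed against
each other with binomial mixed models and information-theoretic multimodel
inference.  It is aimed at invasion ecologists and comparative biologists
who want to run this style of analysis on their own introduction databases —
or audit every step of it on synthetic data with known ground truth.

## The analysis

The unit of analysis is a **species–jurisdiction pair** (one species
introduced to one country, island or US state) with a binary outcome
(established / failed).  Ten candidate factors are scored, coded 1–10
throughout:

| code | factor | code | factor |
|---|---|---|---|
| 1 | min body size (log SVL) | 6 | intentionality of release |
| 2 | congeneric presence | 7 | island vs mainland |
| 3 | min clutch size (log) | 8 | climate matching |
| 4 | distance from native range | 9 | range size (log km²) |
| 5 | habitat breadth (log) | 10 | free-living larval stage |

**Climate matching** uses the DOMAIN envelope: a species' occupied raster
cells (≥ 6 distinct cells, 14 bioclimatic variables) define its envelope;
a cell's similarity to the envelope is `max over training points of
(1 − Gower distance)`, where the Gower distance is the range-normalised
mean absolute difference.  The species–region score is the fraction of the
region's cells whose similarity reaches the envelope's 90th-percentile
leave-one-out threshold, after excluding perfect-similarity cells (which
betray occurrence records from the introduced range itself).  The distance
covariate is `log(1 + d)` with `d` the great-circle distance (km, haversine
on a sphere of radius 6371.0088 km) between range centroids.

**The model** is a Bernoulli GLMM with logit link,

```
logit P(success) = x'β + u_family + u_genus + u_species + u_location
```

with nested taxonomic random intercepts (genus within family, species
within genus) and a crossed location intercept, fitted by maximizing the
Laplace approximation to the marginal likelihood (inner penalized-IRLS
solve for the random-effect modes, outer quasi-Newton over β and log-SDs).
Numeric predictors are standardized to mean 0, SD 0.5 so their
coefficients are comparable with those of untransformed binary factors.

**Multimodel inference**: every subset of the candidate factors (plus the
intercept-only null) is scored by AICc = −2ℓ + 2k + 2k(k+1)/(n−k−1); the
top set keeps models with ΔAICc < 4; Akaike weights `w_i ∝ exp(−Δ_i/2)`
drive full (shrinkage) model averaging with unconditional standard errors
`SE = Σ w_i √(se_i² + (β_i − β̄)²)`, and a factor's relative importance is
the summed weight of top-set models containing it.

A first-class synthetic-data generator emulates every input — smooth
bioclimatic rasters, jurisdictions with island flags and native genus
lists, species with niches and correlated log-normal traits, and outcomes
drawn from a known logit model — so the whole pipeline can be validated
against ground truth.

## Worked example

The numbered scripts under `analysis/` run the full study on a synthetic
world (seed 42: 100 species, 40 jurisdictions, 400 records) and write
their tables under `results/`:

```bash
python analysis/01_simulate_world.py
python analysis/02_climate_match.py
python analysis/03_assemble_dataset.py
python analysis/04_fit_models.py
python analysis/05_average_report.py
```

Script 03 reports the assembled tables and the collinearity screen —
`with_size: 270 rows (67 species, 26 genera)` vs `without_size: 400 rows
(98 species, 29 genera)`, with `body_size ~ clutch_size (r = +0.74)` the
only flagged pair, mirroring why the trait-reduced variant exists.
Script 04 prints, for the trait-complete table:

```
with_size: fitted 32 models in 10 s (0 non-converged, excluded)
  best model: 6+7+8  (AICc 308.21); null model Delta AICc 36.33
```

i.e. the best model combines intentionality (6), island (7) and climate
match (8), and beats the intercept-only model by 36 AICc points.
Script 05 averages the top set:

```
  intentionality[unintentional]    importance 1.00  estimate -1.94 [-2.73, -1.15]
  climate_match                    importance 1.00  estimate +1.81 [+0.89, +2.73]
  intentionality[unknown]          importance 1.00  estimate -0.89 [-1.92, +0.15]
  island                           importance 0.74  estimate +1.17 [-0.68, +3.03]
  variance components (best model): family=0.25, family:genus=0.05,
                                    family:genus:species=0.38, location=2.47
```

Climate match and intentionality sit in every top model (importance 1.0)
with confidence intervals excluding zero — unintentional releases are far
less likely to establish, climatically matched introductions far more —
island shows a positive but less certain effect, and the introduction
location absorbs most of the residual variance while no taxonomic level
explains much: exactly the qualitative structure the generator encodes.

The same pipeline runs from a YAML config (`anurainvade run --config
cfg.yaml`), and the `anurainvade` CLI exposes `simulate`, `climate-match`
and `fit` as individual steps.

## Acceptance script

```bash
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

recomputes the full analysis from scratch: it simulates a study-scale
world from the seed, scores climate match for every record, assembles
both dataset variants, fits the 32-model space over five candidate
factors on each, ranks by AICc, model-averages the top sets, and writes
the report bundle under `results/acceptance_run/` plus the results JSON
at `--out`.

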