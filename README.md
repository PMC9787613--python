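# transleaf

Trans-species tree leaf biomass estimation: a library and CLI for fitting
and applying log-linear allometric leaf-mass models that work across tree
species via numeric functional-trait covariates instead of per-species
equations.

The model family predicts ln(dry leaf mass, kg) from up to eight
predictors — DBH, live crown ratio, crown class (as a five-level variable
intercept), leaf longevity, shade tolerance, wood specific gravity
(observed or published), and site climate (MAT, MAP) — with natural-log
transforms throughout and MAT translated by +30 °C before the log.
Predictions are back-transformed with the Baskerville lognormal bias
correction `exp(sigma² / 2)`.

## What's included

- **Six model specs** (`eq1` … `eq6`): the two full models (observed vs
  published specific gravity) and four reduced models, with packaged
  published coefficient sets usable as ready predictors
  (`transleaf.published_model("eq2")`).
- **Packaged reference tables**: 61-species published traits (leaf
  longevity in months, shade tolerance score, published specific
  gravity; 25 softwoods + 36 hardwoods), keyed by scientific name or
  numeric species code, plus per-species sample sizes and DBH/LCR
  summary moments.
- **Fitting**: OLS on the log scale with cell-means crown-class
  intercepts, fit statistics (adjusted R², RMSE, AIC), backward stepwise
  AIC selection, and generalized-VIF collinearity screening.
- **Validation**: MPE / MAE / MAPE / MAAPE; 10-fold, leave-one-species-out
  (LOSO) and leave-one-group-out cross-validation with training-fold
  Baskerville correction and tree-weighted pooling.
- **Importance**: exact (or seeded-sampled) dominance analysis — model R²
  decomposed into nonnegative per-variable shares by averaging sequential
  R² increments over predictor orderings.
- **Simulation**: a calibrated synthetic-data generator (species mix,
  per-species DBH/LCR distributions, climate ranges, optional low-vigor
  contamination) plus a parameter-recovery harness, so the whole pipeline
  is testable offline.

## CLI

```bash
# synthetic data (deterministic per seed)
transleaf simulate --n 3628 --seed 1 --sigma 0.5 --out sim_trees.csv

# fit the full published-SG model
transleaf fit --input sim_trees.csv --equation eq2 --sg published --out model.json

# predict from a fitted model or a packaged published set
transleaf predict --model table3:eq2 --input sim_trees.csv --correct --out predictions.csv

# cross-validate
transleaf cv --scheme kfold --k 10 --seed 42 --equation eq2 --input sim_trees.csv --out cv.json
transleaf cv --scheme loso --equation eq2 --input sim_trees.csv --out loso.json

# variable importance (dominance analysis)
transleaf importance --equation eq2 --input sim_trees.csv --out importance.json

# inspect packaged tables
transleaf traits
transleaf traits --what coefficients --equation eq2
```

Input tree tables are UTF-8 CSVs with a header; default columns are
`tree_id, species, dbh_cm, lcr, crown_class, sg_obs, leaf_mass_kg,
mat_c, map_mm, study_id` (remappable via `--config` YAML with a
`column_map` entry). Crown class accepts the labels `open_grown`,
`dominant`, `codominant`, `intermediate`, `overtopped` (alias
`suppressed`) or integer codes 1–5 (1 = overtopped … 5 = open grown).
Every output file gets a sibling `*.manifest.json` with options, input
checksums, seeds and the software version.

## Conventions and caveats

- **MAAPE** is reported in radians (mean arctangent, no ×100): the
  published values (0.38–0.52) match this scale even though the printed
  formula carries a ×100 factor. Use `compute_metrics(...,
  maape_times_100=True)` for the literal formula.
- **sigma²** for the Baskerville correction defaults to the unbiased
  residual MSE, RSS/(n−k) (`sigma2_mode="ml"` gives RSS/n). Packaged
  published sets carry sigma² = (published log-scale RMSE)², the only
  printed dispersion.
- **AIC** includes the Gaussian constant and counts the residual variance
  as a parameter; absolute values may differ from other software by a
  data-independent constant, AIC *differences* do not.
- **Crown-class coding** is cell means (five intercepts, no global
  constant) for every equation except the DBH-only model. Predicting a
  crown class unseen at fit time is an error; DBH beyond the calibration
  range (3.05–114.05 cm) only logs an extrapolation warning.
- The source material reports 3628 trees in the text and data summaries
  but 3901 in the coefficient-table caption, and two per-species
  sample-size columns disagree for several species; the packaged tables
  record both values verbatim without reconciling them.
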