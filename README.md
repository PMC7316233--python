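# resistmap

Geostatistical stacked-generalization mapping of insecticide-resistance
phenotypes in mosquito populations over space and time.

The package models proportional mortality from standardized insecticide
susceptibility bioassays (WHO tube tests and CDC bottle bioassays, five
insecticides: four pyrethroids plus DDT), together with *Vgsc*
target-site allele frequencies, on a yearly 2.5 arc-minute grid:

1. **Transforms** — labels pass through an empirical logit (half-count
   correction) followed by the inverse hyperbolic sine; predictions are
   mapped back to the mortality scale with a continuous inverse.
2. **Level-0 ensemble** — three machine-learning constituents fitted jointly
   to all transformed labels (bioassays of every insecticide plus allele
   frequencies, distinguished by a group factor): gradient-boosted trees
   with dropout (DART-style), a random forest (bagged trees with random
   feature subsetting and out-of-bag permutation importance), and a
   componentwise-boosted additive model. Features are lagged gridded
   covariates (lags 0–3 years), principal components of monthly covariates,
   the group factor and the collection year. K-fold out-of-fold predictions
   form the stacking design matrix.
3. **Gaussian-process meta-model** — a Bayesian regression of the
   transformed labels on the out-of-fold level-0 predictions with
   nonnegative weights, plus a separable spatiotemporal Gaussian Markov
   random field (SPDE-type Matérn spatial precision × AR(1) over years)
   and Gaussian noise. Inference is an INLA-style deterministic
   approximation: exact sparse Gaussian conditionals given the four
   hyperparameters, with the hyperparameter posterior explored by Laplace
   approximation plus importance sampling. Separate meta-models are fitted
   to the pyrethroid and DDT bioassay records.
4. **Validation** — K-fold out-of-sample cross-validation with level-0 and
   level-1 refits per fold, RMSE/MAE on both scales, credible-interval
   coverage with and without measurement noise, and PIT histograms.
5. **Map summaries** — per-year fraction of area below a mortality
   threshold (WHO resistance cut-off 0.9) with credible intervals,
   per-country trends, per-pixel maximum interannual change, and variable
   importance weighted by the meta-model weights.

A synthetic-data module generates covariate stacks, latent resistance
surfaces and clustered binomial observations with the same statistical
structure, so the entire pipeline runs at desk scale with no downloads.

## CLI

```bash
resistmap run --config examples/small.yml --out out/        # full pipeline
resistmap simulate --config examples/small.yml --out sim/   # synthetic data only
resistmap validate --config examples/small.yml --out val/   # + cross-validation
```

The artifact directory contains observation CSVs, per-insecticide-per-year
GeoTIFF surfaces (posterior mean and 95% CI bounds), threshold-area trend
tables, interannual-change rasters, meta-model weight summaries, weighted
variable importances and a JSON log of seeds and fitted hyperparameters.
Runs are byte-for-byte reproducible given the config seed.

## Layout

| module | role |
| --- | --- |
| `resistmap.datamodel` | observation records, grid, covariate stack |
| `resistmap.io` | observation CSVs, GeoTIFF rasters |
| `resistmap.transforms` | empirical logit + IHS chain and inverse |
| `resistmap.synthetic` | seeded synthetic data generator |
| `resistmap.gmrf` | separable space–time GMRF precision builders |
| `resistmap.learners` | the three level-0 learners |
| `resistmap.ensemble` | features, folds, tuning, out-of-fold matrix, importances |
| `resistmap.stack` | Bayesian GP meta-model: fit, predict, predictive density |
| `resistmap.validation` | K-fold validation, coverage, PIT |
| `resistmap.summaries` | threshold-area trends, interannual change, weighted importance |
| `resistmap.pipeline` / `resistmap.cli` | config-driven orchestration |
| `resistmap.experiments` | seeded acceptance experiments |
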