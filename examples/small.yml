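# Small synthetic end-to-end configuration (runs in ~10 s).
seed: 3
output_dir: resistmap_output
grid:
  origin_lon: 0.0
  origin_lat: 3.0
  cell_size: 0.25
  n_cols: 12
  n_rows: 12
  years: [2005, 2006, 2007]
synthetic:
  n_covariates: 4
  n_monthly_covariates: 1
  field_sd: 0.8
  field_range: 0.8
  temporal_rho: 0.7
  noise_sd: 0.3
  weight_truth: [0.8, 0.5]
  n_sites: 60
  obs_per_site: 2
  trend: -0.3
  intercept: 2.0
  vgsc_fraction: 0.1
k_folds: 4
stack:
  n_draws: 120
  n_is: 40
map_years: [2005, 2007]
threshold: 0.9
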