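# Small end-to-end demonstration configuration (one CPU, ~1 minute).
seed: 1
simulation:
  n_sites: 12
  n_taxa: 80
  read_depth: 800
  selection_strength: 1.5
  dispersal_scale: 400.0
  fractions: {FL: 1.0, PA: 0.5}
grouping: region
n_perm: 499
spec_occu:
  top_n: 50
  cutoff: 0.7
assembly:
  bin_size_limit: 24
  n_rand: 199
  max_pairs: 60
network:
  threshold: 0.60
  robustness_reps: 100
vpa:
  env_columns: [salinity, temperature, DO, chl_a]
  vif_threshold: 10
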