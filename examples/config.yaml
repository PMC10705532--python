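# Desk-scale end-to-end pipeline configuration for `svkg run`.
# Omitted keys fall back to the full study defaults (40 kb region,
# 14 haplotypes, 240 training samples at 30x).
out_dir: svkg_run
master_seed: 42
coverage: 10.0
n_train: 60
n_heldout: 24
kmer:
  k: 21
  stride: 30
readsim:
  read_length: 150
  insert_mean: 400
  insert_sd: 50
  error_rate: 0.002
training:
  n_folds: 5
  grid:
    - {n_estimators: 100, max_depth: 20, max_features: sqrt}
    - {n_estimators: 100, max_depth: null, max_features: sqrt}
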