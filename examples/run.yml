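# Full-pipeline run configuration: a simulated default cohort, all four
# feature windows, the standard selection threshold and split.
cohort:
  n_patients: 200
  seed: 0
windows: [5, 6, 7, 8]
threshold: 0.9
n_bins: 3
train_fraction: 0.8
normalize_scope: train
seed: 42
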