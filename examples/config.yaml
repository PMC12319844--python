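# Full synthetic pipeline configuration.
seed: 1
out_dir: scratch/run1
simulation:
  n_donors: 6
  samples_per_donor: 80
  n_genes: 1557
  probes_per_gene: 2
  n_step: 53
  n_smooth: 52
  n_mirror: 52
  n_parcels: 20
  noise_sd: 0.5
  batch_sd: 0.25
preprocess:
  noise_level: 0.5
  max_expand_mm: 2.0
select:
  percentile: 90.0
gradients:
  n_boot: 1000
  shuffle_unit: within_region
  n_components: 3
classify:
  train_fraction: 0.8
  c: 1.0
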