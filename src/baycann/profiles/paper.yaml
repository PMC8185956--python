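# Full-scale confirmatory-study profile.
reps: 100
n_adenoma: 500
n_incidence: 100000
n_train: 8000
n_valid: 2000
fidelity_r2: 0.999
target_sigma: sd
training:
  epochs: 2000
  batch_size: 256
  learning_rate: 0.001
  patience: 50
sampler:
  n_draws: 10000
  n_chains: 4
  n_warmup: 1000
imis:
  n0: 1000
  b: 100
  n_resample: 10000
  max_iter: 100
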