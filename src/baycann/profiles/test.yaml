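# Desk-scale profile: exercises the whole pipeline in a few minutes.
reps: 20
n_adenoma: 500
n_incidence: 20000
n_train: 2000
n_valid: 500
fidelity_r2: 0.99
target_sigma: sd
training:
  epochs: 2000
  batch_size: 256
  learning_rate: 0.001
  patience: 50
sampler:
  n_draws: 4000
  n_chains: 2
  n_warmup: 500
imis:
  n0: 500
  b: 100
  n_resample: 4000
  max_iter: 30
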