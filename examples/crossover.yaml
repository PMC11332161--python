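# Study-like cohort: partisanship x strength crossover on discernment,
# cell sizes as recruited, full stimulus set, default MCMC settings.
out_dir: crossover_run
seed: 7
stimulus_set: full_140
cohort:
  cell_sizes:
    democrat/strong: 166
    democrat/weak: 84
    republican/weak: 144
    republican/strong: 104
  baseline:
    d_prime_true: 1.6
    c_true: 0.1
    meta_noise_sigma: 0.33
  effects:
    - {param: d_prime, shift: 0.30, where: {party: democrat}}
    - {param: d_prime, shift: 0.41, where: {party: democrat, strength: strong}}
    - {param: d_prime, shift: 0.21, where: {party: republican, strength: weak}}
mcmc:
  n_chains: 3
  n_samples: 10000
  n_warmup: 2000
analyses:
  favorability: false
  splithalf: false
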