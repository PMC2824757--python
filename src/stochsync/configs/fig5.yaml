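experiment: fig5
seed: 0
out_dir: runs
params:
  kick: 0.3
  amplitude: 20.0
  kappa: 5.0
  lam1: 15.0
  lam2: 15.0
  lam_min: 1.0
  lam_max: 500.0
  tau_lam: 1.0
  n_trials: 100
  n_events: 30000
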