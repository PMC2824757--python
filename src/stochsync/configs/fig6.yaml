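experiment: fig6
seed: 0
out_dir: runs
params:
  kick: 0.5
  amplitude: 80.0
  p: 2.0
  tau_avg: 4800.0
  lam1: 5.0
  lam2: 5.0
  lam_min: 0.3
  lam_max: 500.0
  tau_lam: 2400.0
  n_trials: 100
  n_events: 3000000
  lam_init_range: [0.3, 25.0]
  record_every: 2000
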