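experiment: fig2
seed: 0
out_dir: runs
params:
  topology: 2m1g
  g_sweep: [0.0, 0.5, 2.0]
  n_bins: 24
  t_total: 300.0
  t_total_g0: 1000.0
  dt: 0.0001
  kick: 0.3
  tau_s: 0.005
  sigma: 1.8
  beta: 4.0
  lam_min: 1.5
  lam_max: 200.0
  tau_lam: 1.0
  jump_a: 5.0
  lam_indep: 15.0
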