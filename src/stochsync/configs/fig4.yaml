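experiment: fig4
seed: 0
out_dir: runs
params:
  settings:
  - [0.5, 0.003]
  - [0.55, 0.004]
  - [0.6, 0.005]
  phi_grid: [0.0, 0.7853981633974483, 1.5707963267948966, 2.356194490192345, 3.141592653589793]
  n_seeds: 10
  window_s: 10.0
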