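experiment: fig3
seed: 0
out_dir: runs
params:
  t_total_ms: 300000.0
  dt_ms: 0.025
  sample_ms: 1.0
  corr_width_ms: 500.0
  corr_stride_ms: 250.0
  voltage_thin: 10
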