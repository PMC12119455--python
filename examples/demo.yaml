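# Small end-to-end demo configuration: 6 subjects (2 per group) on the
# default acquisition grid, two simulated readers, full stage list.
out_dir: out
seed: 0
stages: [simulate, fit, extract, reliability, analyze]
protocol:
  n_echoes: 10
  delta_te: 15.0
  tr: 4800.0
  voxel_spacing: [1.5, 1.5, 1.8]
  grid_shape: [64, 64, 16]
cohort:
  groups: {HC: 2, NF1n: 2, NF1p: 2}
  noise_sigma: 0.01
  b1_range: [0.8, 1.1]
  sigma_scale: 1.0
  n_raters: 2
  rater_perturbation: 0.1
fit:
  refine: true
  method: epg
  min_r2: 0.8
  mask_restricted: true
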