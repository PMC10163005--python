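# 400 cells exiting stationary phase through a single permanent nutrient
# shift: first-division statistics and the birth-size/added-volume
# (sizer) correlation.
params:
  preset: stationary
environment:
  kind: constant
  kappa_n0: 160.0
noise:
  threshold_mean: 1.0
  threshold_sd: 0.05
simulation:
  mode: stationary_exit
  n_cells: 400
  t_end: 24.0
  seed: 1
  V_init_range: [0.3, 1.0]
  outdir: scratch/stationary_sizer
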