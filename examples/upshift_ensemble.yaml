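# Generation-averaged response of 400 lineages to a nutrient upshift
# (minimal -> rich medium at t = 3 h): added volume and interdivision
# time overshoot before relaxing to the rich-medium steady state.
params:
  preset: upshift
environment:
  kind: step
  t_shift: 3.0
noise:
  gr_slope_a: 0.15
  gr_intercept_b: 0.02
simulation:
  mode: ensemble
  n_cells: 400
  t_end: 14.0
  seed: 1
  outdir: scratch/upshift_ensemble
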