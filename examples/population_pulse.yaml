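# Branching population (90 founders) through a nutrient-rich pulse:
# the population growth rate transiently decouples from the single-cell
# growth rate at both shifts.
params:
  preset: upshift
environment:
  kind: pulse
  t_shift: 1.0
  tau_feast: 1.5
noise:
  seed: 0
simulation:
  mode: population
  n0: 90
  t_end: 4.0
  seed: 7
  dt: 0.01
  outdir: scratch/population_pulse
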