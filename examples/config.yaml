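# Full mechanistic cohort run: four groups of 9 synthetic animals with the
# published group kinetics, rendered at the default grid and schedule,
# estimated per animal, then ANOVA/LSD/Pearson on the recovered observables.
seed: 1
output_dir: ecstrace_out

cohort:
  mode: mechanistic      # or: empirical (draw all four observables directly)
  n_per_group: 9
  groups: [PD, Madopar, sham, control]

grid:
  grid_shape: 64         # voxels per axis (isotropic)
  voxel_size_mm: 0.2

times:
  n_volumes: 12
  t_start_s: 600.0       # first volume 10 min post-injection
  t_step_s: 900.0        # every 15 min

signal:
  beta: 1.0e10           # signal units per mol/mm^3
  baseline: 100.0
  noise_frac_of_peak: 0.02

estimation:
  mask_threshold: 0.05   # fit voxels above this fraction of the series peak
  theta_noise_multiple: 3.0   # Vd detection threshold: 3 x noise SD
  alpha: 0.2             # ECS volume fraction
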