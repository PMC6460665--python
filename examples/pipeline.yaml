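# Configuration for the CLI pipeline: a reduced cohort that runs in
# seconds.  The `simulation` section mirrors SimulationDesign; the
# `pipeline` section mirrors PipelineConfig.
pipeline:
  voxel_p_threshold: 0.005
  cluster_alpha: 0.05
  n_null_fields: 500
  fdr_q: 0.05
  seed_radius_mm: 6.0
  wm_sphere_radius_mm: 15.0
  polynomial_order: 4
  rng_seed: 7

simulation:
  grid_dims: [20, 24, 20]
  voxel_size_mm: [3.0, 3.0, 3.0]
  n_volumes: 60
  group_sizes: {ASD_F: 4, ASD_M: 5, TD_F: 4, TD_M: 5}
  interaction_delta: 0.15
  rng_seed: 7
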