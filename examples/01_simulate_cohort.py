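"""Generate a small synthetic resting-state cohort and inspect what was
planted.

The generator builds four diagnosis-by-sex cells with a crossover in
cerebellar-cortical coupling: ASD females are shifted +delta and ASD males
-delta on the Fisher-z scale relative to the TD baseline, so the
interaction contrast (ASD_M - TD_M) - (ASD_F - TD_F) equals -2*delta.
"""

from cerefc import CohortSimulation, SimulationDesign, \
    planted_interaction_contrast

design = SimulationDesign(
    n_volumes=60,
    group_sizes={"ASD_F": 3, "ASD_M": 4, "TD_F": 3, "TD_M": 4},
    rng_seed=7,
)
sim = CohortSimulation(design)

print(sim.cohort.to_string(index=False))
print(f"\ngrid: {design.grid.dims} at {design.grid.voxel_size_mm} mm, "
      f"{design.n_volumes} volumes, TR {design.tr_s} s")
print(f"gray voxels: {sim.masks.gray.n_voxels}, "
      f"white: {sim.masks.white.n_voxels}, "
      f"regions: {len(sim.masks.regions)}")

pair = sim.truth.interaction_pairs[0]
print(f"\nplanted pairs: {len(sim.truth.interaction_pairs)} "
      f"(cerebellar-cortical)")
print(f"contrast at {pair}: "
      f"{planted_interaction_contrast(sim.truth, pair):+.2f} z "
      f"(expected -2*delta = {-2 * design.interaction_delta:+.2f})")

subj = sim.subject(0)
print(f"\nfirst subject {subj.subject} ({subj.cell}): "
      f"BOLD array {subj.series.values.shape}, "
      f"motion table {subj.motion.shape}")
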