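# Demo: noiseless slab phantom through the surface pipeline, plus a
# 190-subject synthetic lifespan cohort through stats and trajectories.
out_dir: demo_out
phantom:
  geometry: slab
  thickness_mm: 3.0
  extent_mm: 30.0
  voxel_mm: 1.5
  tilt_deg: 0.0
cohort:
  n_subjects: 190
  seed: 7
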