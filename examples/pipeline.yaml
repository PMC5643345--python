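# End-to-end demo: phantom → two-distance scan → FBP → segmentation →
# indices (≈1 minute). The marrow cavity (inner radius) must stay wider
# than the pore-closing radius (3 × canal diameter = 24 µm here).
phantom:
  grid_shape: [64, 128, 128]
  voxel_size: 1.0
  cortex_outer_radius: 58.0
  cortex_inner_radius: 26.0
  n_canals: 6
  canal_diameter_mean: 8.0
  occupancy_fraction: 0.9
  vessel_fill_fraction: 0.85
  lacunar_density: 40000.0
distance_abs_mm: 0.0
distance_phase_mm: 25.0
n_projections: 181
photons_per_pixel: null   # noiseless; set e.g. 10000.0 for Poisson noise
n_slices: 60
seed: 1
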