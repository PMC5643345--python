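# A small cortical-bone phantom (runs in seconds).
grid_shape: [64, 96, 96]
voxel_size: 1.0
cortex_outer_radius: 44.0
cortex_inner_radius: 20.0
n_canals: 4
canal_diameter_mean: 8.0
canal_diameter_sd: 0.7
canal_orientation_jitter: 2.0
occupancy_fraction: 0.9
vessel_fill_fraction: 0.85
vessel_wall_thickness: 1.0
lacunar_density: 40000.0
lacuna_semi_axes: [4.5, 2.0, 2.0]
rng_seed: 1
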