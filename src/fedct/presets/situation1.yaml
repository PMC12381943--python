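name: situation1
description: >
  Low-mAs-only federation: three clients with distinct imaging geometries
  (including one fan-beam scanner), distinct photon intensities and distinct
  anatomical-region statistics, plus a low-mAs-only server metadata pool.
n_images: 20
metadata_pool: {n_pairs: 24, family: 1}
model:
  base_channels: 8
  shared_channels: 8
  sinogram_units: 2
  image_depth: 4
  shared_units: 2
  filtered_backprojection: true
federation:
  T: 10
  iters_local: 20
  iters_shared: 20
  iters_meta: 20
  omega_c: 0.55
  batch_size: 1
  learning_rate_local: 1.0e-3
  learning_rate_meta: 1.0e-3
loss: {delta: 0.1, alpha_k: 0.5, epsilon_k_paired: 0.0, epsilon_k_unpaired: 0.1}
clients:
- id: client1
  geometry:
    number_of_voxels: 64
    length_of_voxel_mm: 3.0
    number_of_projection_views: 144
    number_of_detector_bins: 95
    length_of_detector_bin_mm: 3.0
    beam: parallel
    reconstruction_filter: ram-lak
  low_dose_protocol: {type: low_mAs, x_ray_intensity: 2.0e+5}
  anatomical_region: 1
  paired: true
- id: client2
  geometry:
    number_of_voxels: 64
    length_of_voxel_mm: 3.0
    number_of_projection_views: 192
    number_of_detector_bins: 127
    length_of_detector_bin_mm: 3.0
    beam: fanflat
    DSD_mm: 1000.0
    DSO_mm: 500.0
    reconstruction_filter: ram-lak
  low_dose_protocol: {type: low_mAs, x_ray_intensity: 1.0e+5}
  anatomical_region: 3
  paired: true
- id: client3
  geometry:
    number_of_voxels: 64
    length_of_voxel_mm: 3.0
    number_of_projection_views: 128
    number_of_detector_bins: 95
    length_of_detector_bin_mm: 3.2
    beam: parallel
    reconstruction_filter: shepp-logan
  low_dose_protocol: {type: low_mAs, x_ray_intensity: 5.0e+4}
  anatomical_region: 2
  paired: true
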