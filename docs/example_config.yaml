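analysis:
  baseline_lateral: generic_one_thickness
  baseline_medial: generic_two_thickness
  histogram_bin_mpa: 0.2
  histogram_start_mpa: 0.2
  isolation_neighbors: 3
  isolation_radius_factor: 3.0
  target_force_n: 0.3
meniscus:
  max_gap_um: 150.0
  superior_clearance_voxels: 2
meshing:
  distal_layers: 2
  surface_normal_tol: 0.05
  surface_smooth_iterations: 4
  surface_smooth_lambda: 0.5
  target_edge_bone_um: 104.4
  target_edge_soft_um: 52.2
  top_layers: 1
phantom:
  cartilage_thickness_femur_mm: 0.1
  cartilage_thickness_tibia_mm: 0.1
  clearance_lateral_um: 18.0
  clearance_medial_um: 20.0
  condyle_radius_lateral_mm: 0.55
  condyle_radius_medial_mm: 0.5
  extra_bone_gap_medial_um: 60.0
  noise_sd: 5.0
  voxel_spacing_um: 17.4
seed: 0
segmentation:
  bone_threshold: null
  cartilage_threshold: 55.0
  mask_smooth_radius_voxels: 2.0
  min_component_voxels: 40
  smoothing_sigma_voxels: 1.0
solver:
  force_rtol: 0.001
  gap_translation_um: 87.0
  loading_displacement_um: 30.0
  max_iterations: 30
  n_init_substeps: 1
  n_steps: 4
  penalty_stiffness: null
variants:
- individual_meniscus
- individual
- generic_two_thickness
- generic_one_thickness
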