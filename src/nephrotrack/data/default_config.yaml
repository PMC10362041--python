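# Calibrated default configuration.
# Cohort layout mirrors the study cohort (~263 IR / ~334 Mid / ~123 Not-IR
# segments across 5-7 mice); injury / cast / proliferation / fate parameters
# are calibrated so that the emergent cohort statistics reproduce the
# published day-0 necrosis means, proximity split, cast accumulation, laser
# response and fate structure.  Edit a copy of this file, not the package
# defaults, to run variants.
protocol: partial_iri_long
seed: 0
cohort:
  n_mice: 7
  nephrons_per_region: {IR: 53, Mid: 67, Not-IR: 25}
  segments_per_nephron: {PT-S1: 2, PT-S2: 2, DCT-CD: 1}
  cells_per_segment: 40
  segment_length_um: 240.0
  cross_section_um2: {PT-S1: 1257.0, PT-S2: 1257.0, DCT-CD: 900.0}
  lumen_fraction: {PT-S1: 0.40, PT-S2: 0.40, DCT-CD: 0.45}
  mouse_sigma: 0.10
injury:
  ischemic_fraction: {IR: 1.0, Mid: 0.50, Not-IR: 0.0, Sham: 0.0}
  severity_scale: {IR: 1.0, Mid: 0.575, Not-IR: 1.0, Sham: 1.0}
  p_necrotic: {PT-S1: 0.85, PT-S2: 0.78, DCT-CD: 0.55}
  body_mean: {PT-S1: 0.350, PT-S2: 0.195, DCT-CD: 0.053}
  body_conc: {PT-S1: 12.0, PT-S2: 20.0, DCT-CD: 30.0}
  severe_weight: {PT-S1: 0.085, PT-S2: 0.15, DCT-CD: 0.0}
  severe_mean: {PT-S1: 0.78, PT-S2: 0.64, DCT-CD: 0.50}
  severe_conc: 20.0
  scattered_prob: 0.0488
  scattered_two_cell_prob: 0.2
  shedding_delay_days: 0.25
casts:
  area_per_shed_cell_um2: 97.0
  production_sigma: 0.35
  transport_um_per_day: 185.0
  deposition_per_um: {PT-S1: 0.00002, PT-S2: 0.0052, DCT-CD: 0.0012}
  deposition_sigma: 1.2
  clearance_recovered_per_day: 0.35
  shed_over_days: 3
  detect_min_fraction: 0.02
proliferation:
  r_prox_um: 25.0
  p_commit_near_per_day: 0.055
  prox_window: [1, 4]
  cast_p_max_per_day: 0.087
  cast_half_dose: 0.17
  cast_hill: 4.0
  baseline_per_day: 0.0046
  latency_days: 1
  visible_days: 1
  response_ramp: {1: 0.25, 2: 0.35, 3: 0.6, 4: 1.36, 5: 0.7, 7: 0.15, 14: 0.02}
fate:
  assignment_day: 4
  logistic_intercept: -5.7
  logistic_cast_coef: 21.0
  logistic_pi0_coef: 0.0
  timing_recovered: {7: 0.77, 14: 0.21, 21: 0.02}
  timing_atrophic: {7: 0.55, 14: 0.34, 21: 0.11}
  severe_cast_threshold: 0.25
  cast_morphology_threshold: 0.04
  necrotic_flag_threshold: 0.01
albumin:
  capillary_intensity: 100.0
  noise_cv: 0.12
  trajectories:
    sham: {0: 1.8, 3: 1.8, 4: 1.8, 7: 1.8, 14: 1.8, 21: 1.8}
    uninjured: {0: 1.75, 3: 1.75, 4: 1.75, 7: 1.8, 14: 1.8, 21: 1.8}
    recovered: {0: 0.50, 3: 0.65, 4: 0.75, 7: 1.75, 14: 1.8, 21: 1.8}
    atrophic: {0: 0.40, 3: 0.35, 4: 0.35, 7: 0.30, 14: 0.25, 21: 0.25}
optics:
  blue_mean: {PT-S1: 120.0, PT-S2: 200.0, DCT-CD: 70.0}
  green_mean: {PT-S1: 100.0, PT-S2: 220.0, DCT-CD: 45.0}
  blue_attenuation: 0.95
  green_attenuation: 0.25
  channel_cv: 0.06
  min_blue: 42.0
  max_ratio: 2.15
  ratio_scale: 0.15
  log_brightness_scale: 0.25
  nucleus_void_level: 0.15
  gfp_track_intensity: 180.0
  cast_intensity: 400.0
  pi_red_intensity: 300.0
  epithelium_940_level: 20.0
  noise_read_sd: 0.0
  noise_poisson_scale: 0.0
laser:
  n_mice: 7
  sites_per_mouse: 10
  n_target_cells: 35
  neighbor_segments_per_mouse: 65
  neighbor_class_mix: {PT-S1: 0.30, PT-S2: 0.55, DCT-CD: 0.15}
  max_distance_um: 135.0
  zone_edges_um: [0.0, 35.0, 85.0, 135.0]
  target_radius_um: 20.0
  transport_um_per_day: 300.0
  shed_over_days: 1
  n_days: 3
observation:
  dropout_rate: 0.0
  count_noise: 0.0
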