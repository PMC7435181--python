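# Default synthetic-canopy configuration (version 1).
# 221 samples, LAI ~ truncated normal (4.90 +/- 1.63, range 1.25-8.76),
# observed at 13 view zenith angles on the 400-900 nm grid.
n_samples: 221
lai_mean: 4.90
lai_sd: 1.63
lai_min: 1.25
lai_max: 8.76
cab_base: 15.0
cab_per_lai: 5.0
cab_sd: 4.0
k_ext: 0.5
clumping: 0.9
soil_intercept: 0.10
soil_slope: 0.00028
soil_brightness_sd: 0.08
asym_h: -0.05
noise_sd0: 0.01
noise_smooth_sd0: 0.045
noise_corr_nm: 35.0
noise_add_sd0: 0.004
noise_gamma: 2.0
seed: 0
leaf:
  nir_plateau: 0.50
  vis_base: 0.08
  blue_center: 450.0
  blue_width: 30.0
  blue_max_depth: 0.055
  red_center: 670.0
  red_width: 25.0
  red_max_depth: 0.065
  green_center: 550.0
  green_width: 25.0
  green_peak: 0.06
  red_edge_center: 705.0
  red_edge_width: 12.0
  red_edge_shift_per_cab: 0.5
  cab_saturation: 8.0
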