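# Example run configuration. Any omitted key falls back to the built-in
# defaults (magrule.config.DEFAULT_CONFIG). Block keys `stains`,
# `cohort.n_per_category` and `optics.objectives` replace the defaults
# wholesale when given.
seed: 1

cohort:
  n_per_category: {"1+": 5, "2+": 6, "3+": 5}
  image_format: png

specimen:
  n_cells: 10
  cell_radius_um: [6.0, 12.0]
  psf_sigma_um: 0.10
  pixel_scale: 5.11
  rgb_noise_sd: 2.0
  canvas_um: 110.0

optics:
  lambda_nm: 600.0
  thresholds_um: [0.4, 1.0, 2.0]   # formula value for 5x would be 2.1429

measure:
  k_rois: 4
  roi_length_um: 6.0
  min_peak_od: 0.05
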