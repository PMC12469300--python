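# Condition presets calibrated to the printed per-condition means of the
# study this pipeline reproduces.  Quantities the source reports only as a
# mean (nuclear-area SD, N/C SD) carry realistic values back-derived from
# the printed standard errors of the mean differences; they are knobs, not
# claims.  Intensity units are arbitrary camera counts; pixel_size in µm/px.
u2os_control:
  nuclear_area_mean: 553.7
  nuclear_area_sd: 110.0
  aspect_ratio_mean: 1.6
  orientation_model: uniform
  target_fd: 1.103
  nc_ratio_mean: 0.26611
  nc_ratio_sd: 0.05
  nuclear_src_fold: 1.0
  cytoplasm_level: 60.0
  background_level: 100.0
  noise_sd: 5.0
  pixel_size: 0.25
u2os_capsaicin:
  nuclear_area_mean: 749.1
  nuclear_area_sd: 110.0
  aspect_ratio_mean: 1.6
  orientation_model: uniform
  target_fd: 1.272
  nc_ratio_mean: 0.4376
  nc_ratio_sd: 0.05
  nuclear_src_fold: 2.0
  cytoplasm_level: 60.0
  background_level: 100.0
  noise_sd: 5.0
  pixel_size: 0.25
u2os_capsaicin_amg:
  # AMG9810 co-treatment returns edge complexity and nuclear Src to baseline
  nuclear_area_mean: 553.7
  nuclear_area_sd: 110.0
  aspect_ratio_mean: 1.6
  orientation_model: uniform
  target_fd: 1.045
  nc_ratio_mean: 0.26611
  nc_ratio_sd: 0.05
  nuclear_src_fold: 1.0
  cytoplasm_level: 60.0
  background_level: 100.0
  noise_sd: 5.0
  pixel_size: 0.25
u2os_stretch:
  # uniaxial cyclic stretch: perpendicular nuclear reorientation
  nuclear_area_mean: 749.1
  nuclear_area_sd: 110.0
  aspect_ratio_mean: 1.6
  orientation_model: perpendicular_biased
  orientation_kappa: 3.0
  target_fd: 1.103
  nc_ratio_mean: 0.4376
  nc_ratio_sd: 0.05
  nuclear_src_fold: 2.0
  cytoplasm_level: 60.0
  background_level: 100.0
  noise_sd: 5.0
  pixel_size: 0.25
saos2_control:
  nuclear_area_mean: 612.0
  nuclear_area_sd: 110.0
  aspect_ratio_mean: 1.6
  orientation_model: uniform
  target_fd: 1.051
  nc_ratio_mean: 0.23349
  nc_ratio_sd: 0.05
  nuclear_src_fold: 1.0
  cytoplasm_level: 60.0
  background_level: 100.0
  noise_sd: 5.0
  pixel_size: 0.25
saos2_capsaicin:
  nuclear_area_mean: 827.0
  nuclear_area_sd: 110.0
  aspect_ratio_mean: 1.6
  orientation_model: uniform
  target_fd: 1.029
  nc_ratio_mean: 0.19188
  nc_ratio_sd: 0.05
  nuclear_src_fold: 0.71
  cytoplasm_level: 60.0
  background_level: 100.0
  noise_sd: 5.0
  pixel_size: 0.25
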