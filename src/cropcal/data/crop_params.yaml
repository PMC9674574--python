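# Default global crop parameters for the calendar rules.
#
# These are literature-consistent defaults in the LPJmL family of global
# gridded crop models; they are deliberately editable and should be
# recalibrated for any serious regional application.
#
# Units: temperatures degC, durations days, P/PET ratios dimensionless.
maize:
  sowing_temp_C: 14.0
  base_temp_C: 5.0
  gf_opt_min_C: 18.0
  gf_opt_max_C: 26.0
  p_pet_sowing: 0.35
  p_pet_maturity: 0.2
  gf_duration_days: 60
  vernalizing: false
  min_duration_days: 90
  max_duration_days: 330
rice:
  sowing_temp_C: 18.0
  base_temp_C: 10.0
  gf_opt_min_C: 22.0
  gf_opt_max_C: 30.0
  p_pet_sowing: 0.35
  p_pet_maturity: 0.2
  gf_duration_days: 40
  vernalizing: false
  min_duration_days: 90
  max_duration_days: 330
sorghum:
  sowing_temp_C: 15.0
  base_temp_C: 10.0
  gf_opt_min_C: 20.0
  gf_opt_max_C: 30.0
  p_pet_sowing: 0.35
  p_pet_maturity: 0.2
  gf_duration_days: 40
  vernalizing: false
  min_duration_days: 90
  max_duration_days: 330
soybean:
  sowing_temp_C: 13.0
  base_temp_C: 10.0
  gf_opt_min_C: 18.0
  gf_opt_max_C: 26.0
  p_pet_sowing: 0.35
  p_pet_maturity: 0.2
  gf_duration_days: 40
  vernalizing: false
  min_duration_days: 90
  max_duration_days: 330
wheat:
  sowing_temp_C: 12.0
  base_temp_C: 0.0
  gf_opt_min_C: 12.0
  gf_opt_max_C: 25.0
  wheat_maturity_max_C: 25.0
  p_pet_sowing: 0.35
  p_pet_maturity: 0.2
  gf_duration_days: 40
  vernalizing: true
  min_duration_days: 90
  max_duration_days: 330
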