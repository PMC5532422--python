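# Full docetaxel monitoring study. Omitted fields use the built-in defaults
# (reported population estimates, literature-plausible surrogate exposure).
study:
  n_patients: 600
  variant: base            # base | half_slope | low_residual | long_mtt
  seed: 2017
  # exposure_scale: 1.02   # omit to calibrate to the Grade-4 incidence target
  target_g4_incidence: 0.68
  scenarios:
    - baseline_only
    - baseline_day5
    - daily:3
    - daily:4
    - daily:5
    - daily:6
    - daily:7
    - daily:10
    - daily:15
    - daily:19
    - q2d:7
    - q2d:15
    - q3d:9
    - q3d:15
pk:
  iiv_cv_cl: 0.30
covariates:
  aag_median: 1.34
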