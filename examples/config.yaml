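# Example shuttlesim run configuration.
# Every key is optional; omitted keys take the documented defaults, which
# reproduce the standard protocol (1 h habituation, 2 h ramping, 30 min gas
# equilibration, 4 h test; 3 degC chamber offset; 0.5 degC/min ramps within
# 15-35 degC; 1 Hz sampling). Unknown keys are rejected.

trial:
  sample_rate: 1.0            # Hz
  phase_durations:            # minutes
    habituation: 60
    ramping: 120
    gas: 30
    test: 240
  chamber_offset: 3.0         # degC, right chamber warmer
  ramp_rate: 0.5              # degC per minute
  temp_limits: [15.0, 35.0]   # degC
  housing_temp: 27.0          # degC
  # initial_left_temp: null   # default: housing_temp - 1.5

population:
  mean_set_point: 27.3        # degC
  between_fish_sd: 1.5        # degC, stable individual differences
  within_fish_sd: 1.4         # degC, phase-to-phase wobble
  treatment_shift: 6.0        # degC subtracted from treated set points
  treatment_speed_shift: 0.15 # added to log swim speed under treatment
  n_control: 20
  n_treated: 17
  quiescence_hazard_control: 0.0
  quiescence_hazard_treated: 1.0e-5   # per second, from gas onset

metrics:
  deadband_cm: 0.0            # midline hysteresis; 0 counts raw crossings
  surface_threshold: 0.9      # normalized depth counting as "at surface"
  velocity_floor: 0.01        # cm/s floor before the log transform

inference:
  n_boot: 1000                # parametric bootstrap draws (repeatability CI)
  n_perm: 1000                # permutations (repeatability p-value)
  rho: 0.95                   # AR(1) coefficient for prewhitening
  basis_dim: 20               # B-spline basis size for the difference smooth
  smooth_bin_s: 60.0          # body-temperature averaging bin (seconds)
  zip_bin_s: 60.0             # shuttle-count bin for the ZIP model (seconds)

asr:
  # rows: [h2s_pct, water_temp_C, n_fish, n_frames]
  design:
    - [0.0, 21.0, 6, 3600]
    - [0.0, 28.0, 6, 3600]
    - [0.02, 21.0, 6, 3600]
    - [0.02, 28.0, 6, 3600]
  # logit-linear truth: intercept, H2S, warm-temperature, interaction
  coefficients: [-3.8918202981106265, 2.833213344056216, 1.252762968495368, 0.0]

output:
  directory: shuttlesim_out
  log_level: info
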