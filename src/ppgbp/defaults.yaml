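# Pipeline defaults. Every tunable that the analysis depends on lives here,
# not in code, so a run is reproducible from this file alone.

filters:
  ppg:
    low_cut: 0.05        # Hz
    high_cut: 30.0       # Hz
    order: 4
  ecg:
    low_cut: 0.05
    high_cut: 140.0
    order: 4
  notch_band: [48.0, 52.0]   # Hz, mains interference stop band
  notch_order: 4

psd:
  segment_seconds: 4.0       # Welch segment length

detection:
  min_peak_distance_s: 0.25  # refractory period between systolic peaks
  # On [0,1]-normalized PPG a systolic peak has prominence near the full
  # dynamic range while even a strong diastolic wave stays below ~0.45.
  peak_prominence: 0.5
  r_peak_height_frac: 0.5    # fraction of max for ECG R-peak candidates
  rr_bounds_s: [0.25, 2.0]   # physiological R-R interval range
  # Notch rule: "zero_crossing" locates the dicrotic notch as the
  # minus-to-plus sign change of the first derivative (the local minimum
  # between systolic and diastolic waves); "derivative_peak" takes the local
  # maximum of the first derivative inside (peak, next valley) instead.
  notch_method: zero_crossing
  outlier_mad_factor: 3.0

features:
  # Zero-crossing rate semantics: "sign_change" counts adjacent-sample sign
  # changes / (N-1); "negative_fraction" counts negative samples / N.
  zcr_semantics: sign_change
  # Statistic estimator conventions, pinned for bit-reproducibility:
  skewness_bias_corrected: true
  kurtosis_convention: pearson   # non-excess (normal -> 3), bias-corrected
  presets:
    # 16 beat-feature families x 4 statistics + the PPG Shannon entropy
    # = 65 named features.  The stiffness index and the "systolic amplitude
    # to diastolic time ratio" share one definition (sa/DT) and enter once;
    # both pulse transit times (to foot and to peak) are included.
    standard:
      beat_features: [systolic_amplitude, diastolic_amplitude, systolic_area,
                      diastolic_area, inflection_point_area, systolic_time,
                      diastolic_time, pulse_interval, stiffness_index,
                      peak_to_peak_interval, pulse_rate, fwhm,
                      augmentation_index, heart_rate, ptt_f, ptt_p]
      statistics: [mean, std, skewness, kurtosis]
      window_scalars: [entropy_ppg]
    # Everything the extractor can compute: the duplicate sa/DT alias, the
    # four zero-crossing rates and the derivative entropies as well.
    full:
      beat_features: [systolic_amplitude, diastolic_amplitude, systolic_area,
                      diastolic_area, inflection_point_area, systolic_time,
                      diastolic_time, pulse_interval, stiffness_index,
                      peak_to_peak_interval, pulse_rate, fwhm, sa_dt_ratio,
                      augmentation_index, heart_rate, ptt_f, ptt_p]
      statistics: [mean, std, skewness, kurtosis]
      window_scalars: [zcr_ppg, zcr_ppg_d1, zcr_ppg_d2, zcr_ecg,
                       entropy_ppg, entropy_ppg_d1, entropy_ppg_d2]

dataset:
  expand_target_n: 870
  sort_key: [dbp_ref, subject_id]   # row ordering before rank interpolation
  outlier_mad_factor: 3.0
  train_frac: 0.85
  split_mode: expand_then_split     # or split_before_expand

reduce:
  n_components: 12
  selection_mode: fixed_k           # or variance_threshold
  variance_threshold: 0.95

gpr:
  sbp:
    kernel_family: matern52
    sigma: 0.1367
  dbp:
    kernel_family: exponential
    sigma: 0.0807
  noise_level: 1.0e-4     # jitter variance for numerical stability
  standardize: true       # scale reduced features to a common std before GP
  # Reduced-feature columns are scaled to this standard deviation, so the
  # sigma grid below spans correlation lengths from well below one
  # feature's spread to several times it.
  input_std: 0.07
  sigma_grid: [0.01, 0.5]
  sigma_grid_points: 25
  cv_folds: 5
  train_phase: before     # the model is fitted on this phase only
  # Model used to predict the later smoking phases: "measured" refits on
  # the measured (unexpanded) training-phase rows — interpolated rows all
  # lie on a 1-D rank curve, which leaves the fitted surface unconstrained
  # off that curve exactly where the other phases live; "expanded" reuses
  # the evaluation model.
  phase_model: measured

synth:
  fs: 500.0               # Hz
  duration: 30.0          # s, one measurement window
  n_subjects: 84
  # Cohort-level baselines (mean, std, [lo, hi] clip):
  heart_rate_bpm: [83.24, 12.61, 50.0, 120.0]
  sbp_mmhg: [121.71, 15.11]      # informational; references come from bp_law
  dbp_mmhg: [75.36, 11.17]
  ptt_p_s: [0.25, 0.035, 0.15, 0.35]
  diastolic_amp: [0.45, 0.06, 0.25, 0.70]
  beat:
    systolic_amp: 1.0
    systolic_center: 0.16        # fraction of beat period
    diastolic_center: 0.46
    systolic_width_frac: 0.075   # fraction of beat period (rendered in s)
    diastolic_width_frac: 0.09
    notch_offset: 0.0            # fraction of beat period added to diastolic_center
  ecg_r_width: 0.012        # s, R-wave Gaussian width
  noise:
    mains_amp: 0.02         # 50 Hz interference amplitude, a.u.
    mains_freq: 50.0
    snr_db: 30.0            # additive Gaussian noise level
  amp_modulation_freq: 0.1  # Hz, slow amplitude modulation carrier
  drift_freq: 0.2           # Hz, baseline drift carrier
  # Per-window nuisance variability around the phase preset (cohort
  # generation only): resting recordings are not identical minute to
  # minute, and without this spread a "before"-trained model would see
  # every later phase as entirely out of distribution.
  window_jitter:
    hr_sd: 3.0          # bpm
    ptt_sd: 0.006       # s
    amp_mod_sd: 0.07    # modulation-depth units
    drift_sd: 0.05      # a.u.
  bp_law:
    # SBP = a0 + a1/PTT_p + a2*AI + eps;  DBP = b0 + b1/PTT_p + b2*AI + eps
    # Coefficients calibrated so the cohort reproduces the demographic
    # means and spreads (SBP 121.7 +/- 15.1, DBP 75.4 +/- 11.2 mmHg) under
    # the configured PTT and augmentation-index distributions.
    sbp: [7.0, 27.0, 3.0]
    dbp: [-8.0, 20.0, 1.5]
    noise_sd_mmhg: 2.0
  phase_presets:
    before:   {hr_shift: 0.0,  amp_modulation_depth: 0.0,  notch_shift: 0.0,
               baseline_drift_amp: 0.0,  ptt_shift: 0.0}
    during:   {hr_shift: 12.0, amp_modulation_depth: 0.12, notch_shift: 0.02,
               baseline_drift_amp: 0.06, ptt_shift: -0.025}
    after_5:  {hr_shift: 8.0,  amp_modulation_depth: 0.12, notch_shift: 0.015,
               baseline_drift_amp: 0.06, ptt_shift: -0.018}
    after_10: {hr_shift: 6.0,  amp_modulation_depth: 0.10, notch_shift: 0.012,
               baseline_drift_amp: 0.05, ptt_shift: -0.014}
    after_20: {hr_shift: 4.0,  amp_modulation_depth: 0.08, notch_shift: 0.008,
               baseline_drift_amp: 0.04, ptt_shift: -0.010}
    after_30: {hr_shift: 2.0,  amp_modulation_depth: 0.06, notch_shift: 0.004,
               baseline_drift_amp: 0.03, ptt_shift: -0.006}
    after_40: {hr_shift: 1.0,  amp_modulation_depth: 0.04, notch_shift: 0.002,
               baseline_drift_amp: 0.02, ptt_shift: -0.003}
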