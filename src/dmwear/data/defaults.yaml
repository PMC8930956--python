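# Default study configuration: synthetic cohort demographics, calibrated
# level-walking templates, simulation and statistics settings.  Angle
# channels are deg, JRF magnitude in body weights; each channel is
# offset + sum_k amp * cos(2*pi*k*(t - phase)) over normalized cycle time.
cohort:
  n_patients: 15
  n_male: 8
  age_mean: 50.0
  age_sd: 14.0
  bmi_mean: 30.0
  bmi_sd: 4.0
  age_bounds: [18.0, 90.0]
  bmi_bounds: [18.0, 45.0]
  height_male: [1.75, 0.07]
  height_female: [1.62, 0.065]
  jrf_scale_sd: 0.12

gait:
  # peak flexion ~30 deg at heel strike, ~-14 deg extension in late stance
  flexion:
    offset: 8.0
    harmonics: [[1, 20.0, 0.03], [2, 3.0, 0.45]]
  abduction:
    offset: 0.0
    harmonics: [[1, 4.0, 0.08]]
  rotation:
    offset: 0.0
    harmonics: [[1, 5.0, 0.55]]
  # double-peaked stance load (~2.5 BW peaks), near-unloaded swing
  jrf_magnitude_bw:
    offset: 1.745
    harmonics: [[1, 0.70, 0.325], [2, -0.745, 0.325]]
  # JRF direction: tilt off the pelvis superior axis toward medial (frontal)
  # and anterior (sagittal)
  jrf_frontal:
    offset: 18.0
    harmonics: [[1, 13.0, 0.30]]
  jrf_sagittal:
    offset: 0.0
    harmonics: [[1, 20.0, 0.10]]
  inter_patient_amp_sd: 0.08
  intra_cycle_noise: 0.02
  cycle_duration: 1.1
  max_angle_amplitude: 60.0
  max_jrf_bw: 4.0

simulation:
  mesh_edge_mm: 0.75
  n_samples: 101          # 100 uniform time steps per cycle
  n_cycles: 1000000       # extrapolation horizon (1.0 Mc ~ one year)
  n_cycles_averaged: 11   # walking cycles averaged into one per patient
  theta_lim_deg: 25.0     # third-articulation engagement threshold
  mu: 0.01                # friction coefficient, all metal-PE interfaces
  pressure_cap: true      # cap contact pressure at the material yield stress
  liner_init: mean        # mobile-liner start: cycle-mean head orientation

implants: {}              # per-construct ImplantSpec field overrides

stats:
  alpha: 0.05
  d_ci_method: normal     # or "noncentral-t"
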