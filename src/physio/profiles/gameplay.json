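{
  "label": "GamePlay",
  "hr_mean": 78.09,
  "hr_between_sd": 6.82,
  "rr_within_sd": 0.04,
  "resp_depth_mean": 1.12,
  "resp_period_mean": 4.0,
  "resp_period_jitter": 0.52,
  "scr_rate": 20.0,
  "scr_amp_mean": 0.6,
  "emg_total_energy_scale": 0.9,
  "emg_fine_fraction": 0.94,
  "temp_offset": 0.48,
  "temp_drift_sd": 0.05
}
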