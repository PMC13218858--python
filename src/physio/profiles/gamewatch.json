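{
  "label": "GameWatch",
  "hr_mean": 74.16,
  "hr_between_sd": 11.06,
  "rr_within_sd": 0.06,
  "resp_depth_mean": 1.29,
  "resp_period_mean": 4.0,
  "resp_period_jitter": 0.41,
  "scr_rate": 12.6,
  "scr_amp_mean": 0.45,
  "emg_total_energy_scale": 1.1,
  "emg_fine_fraction": 0.95,
  "temp_offset": 0.26,
  "temp_drift_sd": 0.05
}
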