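{
  "name": "BCR-666",
  "analyte": "anthophyllite",
  "certified_value_mil_ffg": 5.1,
  "expanded_uncertainty_mil_ffg": 1.5,
  "t_factor": 2.45,
  "replicate_summary": {
    "n": 8,
    "mean_mil_ffg": 5.8,
    "sd_mil_ffg": 0.92,
    "sigma_w0_mil_ffg": 0.72,
    "u_meas_mil_ffg": 0.87
  }
}
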