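{
  "name": "BCR-665",
  "analyte": "amosite + crocidolite",
  "certified_value_mil_ffg": 49.0,
  "expanded_uncertainty_mil_ffg": 16.0,
  "t_factor": 2.45,
  "replicate_summary": {
    "n": 8,
    "mean_mil_ffg": 49.6,
    "sd_mil_ffg": 7.5,
    "sigma_w0_mil_ffg": 7.0,
    "u_meas_mil_ffg": 7.4
  }
}
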