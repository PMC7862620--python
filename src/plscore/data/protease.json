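{
  "provenance": "protease",
  "description": "Protease-specific scoring function, MLR",
  "term_set": [
    "E_coul",
    "E_vdW",
    "E_lipo",
    "E_entropy",
    "E_polar_solv",
    "E_np_solv"
  ],
  "weights": {
    "E_coul": 0.0089,
    "E_vdW": 0.0399,
    "E_lipo": -0.112,
    "E_entropy": 0.0153,
    "E_polar_solv": 0.0515,
    "E_np_solv": 0.0809
  },
  "intercept": -4.8954
}
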