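{
  "provenance": "ippi",
  "description": "PPI-inhibitor-specific scoring function, MLR, two solvation terms",
  "term_set": [
    "E_coul",
    "E_vdW",
    "E_lipo",
    "E_entropy",
    "E_polar_solv",
    "E_np_solv"
  ],
  "weights": {
    "E_coul": 0.0505,
    "E_vdW": 0.0024,
    "E_lipo": -0.013,
    "E_entropy": 0.1967,
    "E_polar_solv": -0.1698,
    "E_np_solv": 1.0569
  },
  "intercept": -0.7898
}
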