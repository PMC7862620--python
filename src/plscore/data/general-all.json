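{
  "provenance": "general-all",
  "description": "General scoring function, MLR, refined-minus-core training set (N = 2764)",
  "term_set": [
    "E_coul",
    "E_vdW",
    "E_lipo",
    "E_entropy",
    "E_polar_solv",
    "E_np_solv"
  ],
  "weights": {
    "E_coul": 0.0045,
    "E_vdW": 0.0343,
    "E_lipo": -0.0104,
    "E_entropy": 0.0605,
    "E_polar_solv": 0.0987,
    "E_np_solv": 0.118
  },
  "intercept": -5.5178
}
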