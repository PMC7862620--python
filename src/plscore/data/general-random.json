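{
  "provenance": "general-random",
  "description": "General scoring function, MLR, random training set (N = 2073)",
  "term_set": [
    "E_coul",
    "E_vdW",
    "E_lipo",
    "E_entropy",
    "E_polar_solv",
    "E_np_solv"
  ],
  "weights": {
    "E_coul": 0.0039,
    "E_vdW": 0.0386,
    "E_lipo": -0.0111,
    "E_entropy": 0.056,
    "E_polar_solv": 0.1025,
    "E_np_solv": 0.0169
  },
  "intercept": -5.5197
}
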