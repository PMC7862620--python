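{
  "provenance": "ippi-onesolv",
  "description": "PPI-inhibitor-specific scoring function, MLR, merged solvation term",
  "term_set": [
    "E_coul",
    "E_vdW",
    "E_lipo",
    "E_entropy",
    "oneSolv"
  ],
  "weights": {
    "E_coul": 0.0335,
    "E_vdW": -0.0207,
    "E_lipo": -0.0153,
    "E_entropy": 0.2038,
    "oneSolv": 1.1227
  },
  "intercept": -1.1397
}
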