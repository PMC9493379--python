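{
  "name": "NIPP dysphagia grade II-IV at 6 months (primary setting)",
  "intercept": -4.05,
  "coefficients": {
    "dmean_oral_cavity": 0.03,
    "dmean_pcm_superior": 0.02,
    "dmean_pcm_medium": 0.01,
    "dmean_pcm_inferior": 0.01,
    "tumour_location": 1.0,
    "baseline_dysphagia": 1.0
  },
  "coding": {
    "tumour_location": {"1": "pharynx", "0": "larynx"},
    "baseline_dysphagia": {"1": "baseline grade >= 2", "0": "baseline grade < 2"}
  }
}
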