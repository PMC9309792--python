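{
  "_provenance": "Average tissue densities in g/cm^3 used to convert segmented tissue volumes to segment masses: aerated lung 0.25, adipose 0.96, remaining soft tissue 1.06, bone 1.5.",
  "lung": 0.25,
  "fat": 0.96,
  "soft": 1.06,
  "bone": 1.5
}
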