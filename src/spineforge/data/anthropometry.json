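{
  "_provenance": "Segment mass fractions from standard anthropometric tables (Winter, Biomechanics and Motor Control of Human Movement): head+neck 8.1% of body mass, each whole upper limb 5.0% of body mass, trunk 49.7% of body mass. Whole-body mass is inferred from the CT-derived torso mass through the trunk fraction; generic bodies scale geometrically with stature against a 1.75 m reference.",
  "torso_fraction": 0.497,
  "reference_stature_m": 1.75,
  "segments": {
    "head_neck": {"fraction": 0.081, "reference": "body", "count": 1},
    "arm": {"fraction": 0.050, "reference": "body", "count": 2}
  }
}
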