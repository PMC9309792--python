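{
  "_provenance": "Rotational neutral zones (deg) and post-neutral-zone stiffnesses (N*m/deg) per intervertebral level, in the range reported by in vitro flexibility testing of lumbar functional spinal units (Panjabi-style protocols). Axes: x frontal (lateral bending), y axial rotation, z sagittal (flexion-extension).",
  "discs": {
    "T12/L1": {"neutral_zone_deg": [1.4, 0.9, 1.4], "stiffness_nm_per_deg": [1.9, 4.0, 1.7]},
    "L1/L2":  {"neutral_zone_deg": [1.5, 0.9, 1.5], "stiffness_nm_per_deg": [1.9, 4.0, 1.7]},
    "L2/L3":  {"neutral_zone_deg": [1.5, 1.0, 1.5], "stiffness_nm_per_deg": [2.0, 4.2, 1.8]},
    "L3/L4":  {"neutral_zone_deg": [1.6, 1.0, 1.6], "stiffness_nm_per_deg": [2.1, 4.4, 1.8]},
    "L4/L5":  {"neutral_zone_deg": [1.6, 1.1, 1.7], "stiffness_nm_per_deg": [2.2, 4.6, 1.9]},
    "L5/S1":  {"neutral_zone_deg": [1.7, 1.1, 1.8], "stiffness_nm_per_deg": [2.3, 4.8, 2.0]}
  }
}
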