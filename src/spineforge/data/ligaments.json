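{
  "_provenance": "Breakpoint strains/forces per ligament follow the cadaveric tensile literature on spinal ligaments (Chazal et al., J Biomech 1985 range); pre-strains follow reported neutral-posture strain measurements (Nachemson & Evans 1968; Tkaczuk 1968; Panjabi et al. 1982). The flaval pre-strain default is 5% - the reduced value that keeps flaval forces physiological in upright-flexion use; the supraspinous ligament is the one spinal ligament with negative neutral pre-strain. Forces are whole-ligament values at the toe-to-linear transition (A) and at the end of the linear region before failure (B); n is the number of parallel components sharing the load.",
  "ligaments": {
    "ALL": {
      "eps_pre": 0.02, "eps_A": 0.12, "eps_B": 0.36, "F_A": 120.0, "F_B": 450.0, "n": 1,
      "attachment_inferior": "body_rim_ant_sup", "attachment_superior": "body_rim_ant_inf",
      "sacrum_attachment": "body_rim_ant_sup"
    },
    "PLL": {
      "eps_pre": 0.02, "eps_A": 0.11, "eps_B": 0.33, "F_A": 90.0, "F_B": 300.0, "n": 1,
      "attachment_inferior": "body_rim_post_sup", "attachment_superior": "body_rim_post_inf",
      "sacrum_attachment": "body_rim_post_sup"
    },
    "LF": {
      "eps_pre": 0.05, "eps_A": 0.10, "eps_B": 0.30, "F_A": 80.0, "F_B": 260.0, "n": 2,
      "attachment_inferior": "arch_superior", "attachment_superior": "arch_inferior",
      "sacrum_attachment": "body_rim_post_sup"
    },
    "ISL": {
      "eps_pre": 0.01, "eps_A": 0.10, "eps_B": 0.30, "F_A": 40.0, "F_B": 130.0, "n": 1,
      "attachment_inferior": "spinous_superior", "attachment_superior": "spinous_inferior",
      "sacrum_attachment": "body_rim_post_sup"
    },
    "SSL": {
      "eps_pre": -0.05, "eps_A": 0.12, "eps_B": 0.36, "F_A": 70.0, "F_B": 230.0, "n": 1,
      "attachment_inferior": "spinous_posterior", "attachment_superior": "spinous_posterior",
      "sacrum_attachment": "body_rim_post_sup"
    }
  }
}
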