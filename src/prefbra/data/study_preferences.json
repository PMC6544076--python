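{
  "comment": "Published summary of elicited indifference amounts (MIR/MRB) per attribute and age group: mean, SD (n-1 denominator), and number of respondents who completed the attribute. Proportion attributes in 0-1 units, proven_to_work in years. n_total is the survey sample size; under60_fraction its age mix.",
  "n_total": 219,
  "under60_fraction": 0.603,
  "mir_summary": {
    "mortality": {
      "all":     {"mean": 0.0386, "sd": 0.0295, "n": 109},
      "under60": {"mean": 0.034,  "sd": 0.027,  "n": 65},
      "ge60":    {"mean": 0.045,  "sd": 0.032,  "n": 44}
    },
    "stroke": {
      "all":     {"mean": 0.0669, "sd": 0.0573, "n": 110},
      "under60": {"mean": 0.065,  "sd": 0.056,  "n": 67},
      "ge60":    {"mean": 0.070,  "sd": 0.060,  "n": 43}
    },
    "independence": {
      "all":     {"mean": 0.1394, "sd": 0.1177, "n": 131},
      "under60": {"mean": 0.135,  "sd": 0.115,  "n": 80},
      "ge60":    {"mean": 0.146,  "sd": 0.122,  "n": 51}
    },
    "pacemaker": {
      "all":     {"mean": 0.0698, "sd": 0.0571, "n": 132},
      "under60": {"mean": 0.059,  "sd": 0.051,  "n": 76},
      "ge60":    {"mean": 0.084,  "sd": 0.062,  "n": 56}
    },
    "dialysis": {
      "all":     {"mean": 0.0621, "sd": 0.0562, "n": 131},
      "under60": {"mean": 0.054,  "sd": 0.051,  "n": 81},
      "ge60":    {"mean": 0.075,  "sd": 0.062,  "n": 50}
    },
    "proven_to_work": {
      "all":     {"mean": 17.42, "sd": 16.86, "n": 131},
      "under60": {"mean": 17.9,  "sd": 16.7,  "n": 80},
      "ge60":    {"mean": 16.6,  "sd": 17.2,  "n": 51}
    }
  },
  "straight_liner_fraction": 0.0868
}
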