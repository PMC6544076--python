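{
  "attributes": [
    {"name": "procedure", "direction": "benefit", "worst": 0.0, "best": 1.0,
     "units": "binary-procedure"},
    {"name": "mortality", "direction": "risk", "worst": 0.053, "best": 0.005,
     "units": "proportion"},
    {"name": "stroke", "direction": "risk", "worst": 0.044, "best": 0.002,
     "units": "proportion"},
    {"name": "independence", "direction": "benefit", "worst": 0.227, "best": 0.500,
     "units": "proportion"},
    {"name": "pacemaker", "direction": "risk", "worst": 0.142, "best": 0.072,
     "units": "proportion"},
    {"name": "dialysis", "direction": "risk", "worst": 0.060, "best": 0.021,
     "units": "proportion"},
    {"name": "proven_to_work", "direction": "benefit", "worst": 5.0, "best": 30.0,
     "units": "years"}
  ],
  "alternatives": [
    {"name": "TAVR", "performance": {
      "procedure": {"mean": 1.0},
      "mortality": {"mean": 0.011, "ci_low": 0.005, "ci_high": 0.017},
      "stroke": {"mean": 0.008, "ci_low": 0.002, "ci_high": 0.013},
      "independence": {"mean": 0.479, "ci_low": 0.454, "ci_high": 0.500},
      "pacemaker": {"mean": 0.123, "ci_low": 0.103, "ci_high": 0.142},
      "dialysis": {"mean": 0.032, "ci_low": 0.021, "ci_high": 0.042},
      "proven_to_work": {"mean": 10.0}
    }},
    {"name": "SAVR", "performance": {
      "procedure": {"mean": 0.0},
      "mortality": {"mean": 0.040, "ci_low": 0.028, "ci_high": 0.053},
      "stroke": {"mean": 0.033, "ci_low": 0.021, "ci_high": 0.044},
      "independence": {"mean": 0.249, "ci_low": 0.227, "ci_high": 0.276},
      "pacemaker": {"mean": 0.090, "ci_low": 0.072, "ci_high": 0.108},
      "dialysis": {"mean": 0.047, "ci_low": 0.034, "ci_high": 0.060},
      "proven_to_work": {"mean": 20.0}
    }}
  ],
  "transforms": {
    "stroke_case_fatality": 0.0,
    "kccq_cutoff": 75.0
  }
}
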