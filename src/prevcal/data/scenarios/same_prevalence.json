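{
  "name": "same_prevalence",
  "description": "Internal vs external validation at identical prevalence: every metric varies in the same direction as sensitivity/specificity.",
  "expected_flags": [],
  "runs": [
    {
      "label": "internal",
      "profile": {
        "sen": 0.71,
        "spe": 0.89,
        "pre": 0.9,
        "n": 2000.0
      }
    },
    {
      "label": "external",
      "profile": {
        "sen": 0.68,
        "spe": 0.85,
        "pre": 0.9,
        "n": 1000.0
      }
    }
  ]
}
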