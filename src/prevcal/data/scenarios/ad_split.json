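{
  "name": "ad_split",
  "description": "Applicability-domain filtering halves coverage and shifts prevalence 0.600 -> 0.900: raw MCC falls 0.520 -> 0.377 while balanced MCC rises 0.538 -> 0.610.",
  "expected_flags": [
    "prevalence_shift",
    "raw_metric_contradiction"
  ],
  "runs": [
    {
      "label": "full",
      "profile": {
        "sen": 0.68,
        "spe": 0.85,
        "pre": 0.6,
        "n": 2000.0
      }
    },
    {
      "label": "in_domain",
      "profile": {
        "sen": 0.71,
        "spe": 0.89,
        "pre": 0.9,
        "n": 1000.0
      }
    }
  ]
}
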