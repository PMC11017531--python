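{
  "name": "shifted_prevalence",
  "description": "External prevalence drops 0.900 -> 0.600: sensitivity and specificity both fall yet raw MCC/accuracy/PPV/kappa rise.",
  "expected_flags": [
    "prevalence_shift",
    "raw_metric_contradiction"
  ],
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
        "pre": 0.6,
        "n": 1000.0
      }
    }
  ]
}
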