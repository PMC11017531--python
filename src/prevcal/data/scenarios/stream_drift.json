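{
  "name": "stream_drift",
  "description": "Ten stream windows with prevalence drifting 0.3 -> 0.9 at fixed sen/spe: raw accuracy drifts monotonically, balanced accuracy is constant. Windows are integer-realised by largest-remainder rounding.",
  "expected_flags": [
    "prevalence_shift"
  ],
  "runs": [
    {
      "label": "window_01",
      "profile": {
        "sen": 0.75,
        "spe": 0.85,
        "pre": 0.3,
        "n": 500.0
      }
    },
    {
      "label": "window_02",
      "profile": {
        "sen": 0.75,
        "spe": 0.85,
        "pre": 0.3666666666666667,
        "n": 500.0
      }
    },
    {
      "label": "window_03",
      "profile": {
        "sen": 0.75,
        "spe": 0.85,
        "pre": 0.43333333333333335,
        "n": 500.0
      }
    },
    {
      "label": "window_04",
      "profile": {
        "sen": 0.75,
        "spe": 0.85,
        "pre": 0.5,
        "n": 500.0
      }
    },
    {
      "label": "window_05",
      "profile": {
        "sen": 0.75,
        "spe": 0.85,
        "pre": 0.5666666666666667,
        "n": 500.0
      }
    },
    {
      "label": "window_06",
      "profile": {
        "sen": 0.75,
        "spe": 0.85,
        "pre": 0.6333333333333333,
        "n": 500.0
      }
    },
    {
      "label": "window_07",
      "profile": {
        "sen": 0.75,
        "spe": 0.85,
        "pre": 0.7000000000000001,
        "n": 500.0
      }
    },
    {
      "label": "window_08",
      "profile": {
        "sen": 0.75,
        "spe": 0.85,
        "pre": 0.7666666666666668,
        "n": 500.0
      }
    },
    {
      "label": "window_09",
      "profile": {
        "sen": 0.75,
        "spe": 0.85,
        "pre": 0.8333333333333335,
        "n": 500.0
      }
    },
    {
      "label": "window_10",
      "profile": {
        "sen": 0.75,
        "spe": 0.85,
        "pre": 0.9,
        "n": 500.0
      }
    }
  ]
}
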