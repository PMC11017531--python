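{
  "$schema": "http://json-schema.org/draft-07/schema#",
  "title": "prevcal comparison-report document",
  "type": "object",
  "required": [
    "runs",
    "metrics",
    "verdict",
    "flags"
  ],
  "properties": {
    "runs": {
      "type": "array",
      "items": {
        "type": "object",
        "required": [
          "label",
          "matrix"
        ],
        "properties": {
          "label": {
            "type": "string"
          },
          "source": {
            "type": "string"
          },
          "matrix": {
            "type": "object",
            "required": [
              "tp",
              "fn",
              "fp",
              "tn"
            ],
            "properties": {
              "tp": {
                "type": "number",
                "minimum": 0
              },
              "fn": {
                "type": "number",
                "minimum": 0
              },
              "fp": {
                "type": "number",
                "minimum": 0
              },
              "tn": {
                "type": "number",
                "minimum": 0
              },
              "calibrated": {
                "type": "boolean"
              },
              "metadata": {
                "type": "object"
              }
            }
          }
        }
      }
    },
    "metrics": {
      "type": "array",
      "items": {
        "type": "object",
        "required": [
          "metric",
          "kind",
          "values",
          "variation"
        ],
        "properties": {
          "metric": {
            "type": "string"
          },
          "kind": {
            "enum": [
              "statistic",
              "raw",
              "balanced"
            ]
          },
          "values": {
            "type": "array",
            "items": {
              "type": [
                "number",
                "null"
              ]
            }
          },
          "variation": {
            "enum": [
              "increase",
              "decrease",
              "constant",
              "undefined"
            ]
          }
        }
      }
    },
    "verdict": {
      "enum": [
        "better",
        "worse",
        "trade_off",
        null
      ]
    },
    "flags": {
      "type": "array",
      "items": {
        "type": "string"
      }
    },
    "config": {
      "type": "object",
      "properties": {
        "reference_prevalence": {
          "type": "number",
          "minimum": 0,
          "maximum": 1
        },
        "shift_threshold": {
          "type": "number",
          "minimum": 0
        },
        "variation_tolerance": {
          "type": "number",
          "minimum": 0
        }
      }
    }
  }
}
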