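{
  "$schema": "http://json-schema.org/draft-07/schema#",
  "title": "prevcal scenario document",
  "type": "object",
  "required": [
    "name",
    "runs"
  ],
  "properties": {
    "name": {
      "type": "string"
    },
    "description": {
      "type": "string"
    },
    "expected_flags": {
      "type": "array",
      "items": {
        "type": "string"
      }
    },
    "runs": {
      "type": "array",
      "items": {
        "type": "object",
        "required": [
          "label",
          "profile"
        ],
        "properties": {
          "label": {
            "type": "string"
          },
          "profile": {
            "type": "object",
            "required": [
              "sen",
              "spe",
              "pre",
              "n"
            ],
            "properties": {
              "sen": {
                "type": [
                  "number",
                  "null"
                ],
                "minimum": 0,
                "maximum": 1
              },
              "spe": {
                "type": [
                  "number",
                  "null"
                ],
                "minimum": 0,
                "maximum": 1
              },
              "pre": {
                "type": "number",
                "minimum": 0,
                "maximum": 1
              },
              "n": {
                "type": "number"
              }
            }
          }
        }
      }
    }
  }
}
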