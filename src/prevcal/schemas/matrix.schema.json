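{
  "$schema": "http://json-schema.org/draft-07/schema#",
  "title": "prevcal confusion-matrix document",
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
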