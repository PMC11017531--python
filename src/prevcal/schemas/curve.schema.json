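{
  "$schema": "http://json-schema.org/draft-07/schema#",
  "title": "prevcal sweep-curve document",
  "type": "object",
  "required": [
    "metric",
    "sen",
    "spe",
    "grid",
    "values"
  ],
  "properties": {
    "metric": {
      "type": "string"
    },
    "sen": {
      "type": "number",
      "minimum": 0,
      "maximum": 1
    },
    "spe": {
      "type": "number",
      "minimum": 0,
      "maximum": 1
    },
    "grid": {
      "type": "array",
      "items": {
        "type": "number",
        "minimum": 0,
        "maximum": 1
      }
    },
    "values": {
      "type": "array",
      "items": {
        "type": "number"
      }
    }
  }
}
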