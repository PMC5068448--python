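{
  "$schema": "http://json-schema.org/draft-07/schema#",
  "title": "GGBN gel-image quality record",
  "type": "object",
  "required": ["DNAThreshold", "percentAboveThreshold", "ladder", "image", "lane", "method", "warnings"],
  "properties": {
    "DNAThreshold": {"type": "integer", "minimum": 1},
    "percentAboveThreshold": {"type": ["number", "null"], "minimum": 0, "maximum": 100},
    "ladder": {"type": "string"},
    "image": {"type": "string"},
    "lane": {"type": "string"},
    "genomicQuality": {"type": ["boolean", "null"]},
    "areaAbove": {"type": "number", "minimum": 0},
    "areaBelow": {"type": "number", "minimum": 0},
    "method": {
      "type": "object",
      "required": ["software", "softwareVersion"],
      "properties": {
        "software": {"type": "string"},
        "softwareVersion": {"type": "string"},
        "boxWidth_px": {"type": "integer"},
        "rowTop_px": {"type": "integer"},
        "rowBottom_px": {"type": "integer"},
        "backgroundRadius_px": {"type": "number"},
        "profileStatistic": {"type": "string"}
      }
    },
    "warnings": {"type": "array", "items": {"type": "string"}}
  }
}
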