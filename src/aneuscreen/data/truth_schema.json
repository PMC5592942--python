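{
  "$schema": "https://json-schema.org/draft/2020-12/schema",
  "title": "aneuscreen truth file",
  "type": "object",
  "required": ["events"],
  "properties": {
    "events": {
      "type": "array",
      "items": {
        "type": "object",
        "required": ["event_type", "chrom", "start", "end", "alt", "copy_number"],
        "properties": {
          "event_type": {"enum": ["snv", "insertion", "deletion", "disomy", "segmental_dup"]},
          "chrom": {"type": "string"},
          "start": {"type": "integer", "minimum": 1},
          "end": {"type": "integer", "minimum": 1},
          "alt": {"type": "string"},
          "copy_number": {"type": "integer", "minimum": 1},
          "effect_class": {"type": ["string", "null"]}
        }
      }
    }
  }
}
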