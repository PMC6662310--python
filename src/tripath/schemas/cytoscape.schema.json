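{
  "$schema": "http://json-schema.org/draft-07/schema#",
  "title": "tripath Cytoscape export",
  "type": "object",
  "required": ["format_version", "pathway_id", "elements"],
  "properties": {
    "format_version": {"type": "string"},
    "pathway_id": {"type": "string"},
    "elements": {
      "type": "object",
      "required": ["nodes", "edges"],
      "properties": {
        "nodes": {
          "type": "array",
          "items": {
            "type": "object",
            "required": ["data"],
            "properties": {
              "data": {
                "type": "object",
                "required": ["id", "type"],
                "properties": {
                  "id": {"type": "string"},
                  "type": {"enum": ["gene", "regulator"]},
                  "consistency": {"type": "number"},
                  "impact": {"type": "number"},
                  "triangulation": {"type": "number"},
                  "p": {"type": ["number", "null"]},
                  "n_regulators": {"type": "integer"},
                  "chrom": {"type": "string"},
                  "start": {"type": "integer"},
                  "end": {"type": "integer"}
                }
              }
            }
          }
        },
        "edges": {
          "type": "array",
          "items": {
            "type": "object",
            "required": ["data"],
            "properties": {
              "data": {
                "type": "object",
                "required": ["id", "source", "target", "interaction"],
                "properties": {
                  "id": {"type": "string"},
                  "source": {"type": "string"},
                  "target": {"type": "string"},
                  "interaction": {"enum": ["activation", "inhibition", "noncoding"]},
                  "provenance": {"enum": ["loop", "proximity"]}
                }
              }
            }
          }
        }
      }
    }
  }
}
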