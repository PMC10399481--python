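{
  "$defs": {
    "RankedCompound": {
      "properties": {
        "compound_id": {
          "title": "Compound Id",
          "type": "string"
        },
        "score": {
          "title": "Score",
          "type": "number"
        }
      },
      "required": [
        "compound_id",
        "score"
      ],
      "title": "RankedCompound",
      "type": "object"
    },
    "StageReport": {
      "properties": {
        "compound_ids": {
          "items": {
            "type": "string"
          },
          "title": "Compound Ids",
          "type": "array"
        },
        "count": {
          "title": "Count",
          "type": "integer"
        },
        "name": {
          "title": "Name",
          "type": "string"
        }
      },
      "required": [
        "name",
        "count",
        "compound_ids"
      ],
      "title": "StageReport",
      "type": "object"
    }
  },
  "properties": {
    "final_ranked": {
      "items": {
        "$ref": "#/$defs/RankedCompound"
      },
      "title": "Final Ranked",
      "type": "array"
    },
    "schema_version": {
      "default": "1",
      "title": "Schema Version",
      "type": "string"
    },
    "seed": {
      "title": "Seed",
      "type": "integer"
    },
    "settings": {
      "additionalProperties": true,
      "title": "Settings",
      "type": "object"
    },
    "stages": {
      "items": {
        "$ref": "#/$defs/StageReport"
      },
      "title": "Stages",
      "type": "array"
    }
  },
  "required": [
    "seed",
    "settings",
    "stages",
    "final_ranked"
  ],
  "title": "ScreeningReport",
  "type": "object"
}
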