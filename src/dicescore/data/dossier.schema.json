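{
  "$defs": {
    "_EffectModel": {
      "additionalProperties": false,
      "properties": {
        "odds_ratio": {
          "title": "Odds Ratio",
          "type": "number"
        },
        "ci_lower": {
          "title": "Ci Lower",
          "type": "number"
        },
        "ci_upper": {
          "title": "Ci Upper",
          "type": "number"
        },
        "ci_level": {
          "default": 0.95,
          "title": "Ci Level",
          "type": "number"
        },
        "label": {
          "default": "",
          "title": "Label",
          "type": "string"
        }
      },
      "required": [
        "odds_ratio",
        "ci_lower",
        "ci_upper"
      ],
      "title": "_EffectModel",
      "type": "object"
    },
    "_FactorModel": {
      "additionalProperties": false,
      "properties": {
        "name": {
          "minLength": 1,
          "title": "Name",
          "type": "string"
        },
        "factor_class": {
          "default": "other",
          "enum": [
            "gene",
            "variant",
            "exposure",
            "pathway",
            "other"
          ],
          "title": "Factor Class",
          "type": "string"
        },
        "aliases": {
          "default": [],
          "items": {
            "type": "string"
          },
          "title": "Aliases",
          "type": "array"
        }
      },
      "required": [
        "name"
      ],
      "title": "_FactorModel",
      "type": "object"
    },
    "_ItemModel": {
      "additionalProperties": false,
      "properties": {
        "item_id": {
          "minLength": 1,
          "title": "Item Id",
          "type": "string"
        },
        "category": {
          "enum": [
            "omic",
            "informatic",
            "experimental"
          ],
          "title": "Category",
          "type": "string"
        },
        "subtype": {
          "title": "Subtype",
          "type": "string"
        },
        "result_key": {
          "minLength": 1,
          "title": "Result Key",
          "type": "string"
        },
        "p_value": {
          "anyOf": [
            {
              "exclusiveMinimum": 0.0,
              "maximum": 1.0,
              "type": "number"
            },
            {
              "type": "null"
            }
          ],
          "default": null,
          "title": "P Value"
        },
        "significant_override": {
          "anyOf": [
            {
              "type": "boolean"
            },
            {
              "type": "null"
            }
          ],
          "default": null,
          "title": "Significant Override"
        },
        "effect": {
          "anyOf": [
            {
              "$ref": "#/$defs/_EffectModel"
            },
            {
              "type": "null"
            }
          ],
          "default": null
        },
        "source": {
          "default": "",
          "title": "Source",
          "type": "string"
        },
        "reviewed": {
          "default": true,
          "title": "Reviewed",
          "type": "boolean"
        }
      },
      "required": [
        "item_id",
        "category",
        "subtype",
        "result_key"
      ],
      "title": "_ItemModel",
      "type": "object"
    },
    "_PhenotypeModel": {
      "additionalProperties": false,
      "properties": {
        "name": {
          "minLength": 1,
          "title": "Name",
          "type": "string"
        },
        "description": {
          "default": "",
          "title": "Description",
          "type": "string"
        }
      },
      "required": [
        "name"
      ],
      "title": "_PhenotypeModel",
      "type": "object"
    }
  },
  "additionalProperties": false,
  "properties": {
    "factor": {
      "$ref": "#/$defs/_FactorModel"
    },
    "phenotype": {
      "$ref": "#/$defs/_PhenotypeModel"
    },
    "items": {
      "default": [],
      "items": {
        "$ref": "#/$defs/_ItemModel"
      },
      "title": "Items",
      "type": "array"
    },
    "notes": {
      "default": "",
      "title": "Notes",
      "type": "string"
    }
  },
  "required": [
    "factor",
    "phenotype"
  ],
  "title": "Evidence dossier",
  "type": "object",
  "$schema": "https://json-schema.org/draft/2020-12/schema"
}
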