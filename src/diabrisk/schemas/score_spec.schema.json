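{
  "$defs": {
    "ProbabilityLink": {
      "additionalProperties": false,
      "properties": {
        "kind": {
          "enum": [
            "direct_logistic",
            "score_logistic"
          ],
          "title": "Kind",
          "type": "string"
        },
        "a": {
          "default": 0.0,
          "title": "A",
          "type": "number"
        },
        "b": {
          "default": 1.0,
          "title": "B",
          "type": "number"
        }
      },
      "required": [
        "kind"
      ],
      "title": "ProbabilityLink",
      "type": "object"
    },
    "ScoreItem": {
      "additionalProperties": false,
      "properties": {
        "predictor": {
          "title": "Predictor",
          "type": "string"
        },
        "kind": {
          "enum": [
            "threshold_points",
            "categorical_points",
            "linear_coefficient"
          ],
          "title": "Kind",
          "type": "string"
        },
        "cut_points": {
          "anyOf": [
            {
              "items": {
                "type": "number"
              },
              "type": "array"
            },
            {
              "type": "null"
            }
          ],
          "default": null,
          "title": "Cut Points"
        },
        "values": {
          "anyOf": [
            {
              "items": {
                "type": "number"
              },
              "type": "array"
            },
            {
              "additionalProperties": {
                "type": "number"
              },
              "type": "object"
            },
            {
              "type": "null"
            }
          ],
          "default": null,
          "title": "Values"
        },
        "coefficient": {
          "anyOf": [
            {
              "type": "number"
            },
            {
              "type": "null"
            }
          ],
          "default": null,
          "title": "Coefficient"
        },
        "sex_specific": {
          "anyOf": [
            {
              "additionalProperties": {
                "items": {
                  "type": "number"
                },
                "type": "array"
              },
              "type": "object"
            },
            {
              "type": "null"
            }
          ],
          "default": null,
          "title": "Sex Specific"
        }
      },
      "required": [
        "predictor",
        "kind"
      ],
      "title": "ScoreItem",
      "type": "object"
    }
  },
  "additionalProperties": false,
  "description": "Declarative definition of one risk prediction model.",
  "properties": {
    "name": {
      "title": "Name",
      "type": "string"
    },
    "form": {
      "enum": [
        "points",
        "logistic"
      ],
      "title": "Form",
      "type": "string"
    },
    "items": {
      "items": {
        "$ref": "#/$defs/ScoreItem"
      },
      "minItems": 1,
      "title": "Items",
      "type": "array"
    },
    "intercept": {
      "default": 0.0,
      "title": "Intercept",
      "type": "number"
    },
    "probability_link": {
      "$ref": "#/$defs/ProbabilityLink"
    },
    "description": {
      "default": "",
      "title": "Description",
      "type": "string"
    },
    "citation": {
      "default": "",
      "title": "Citation",
      "type": "string"
    },
    "provisional": {
      "default": false,
      "title": "Provisional",
      "type": "boolean"
    }
  },
  "required": [
    "name",
    "form",
    "items",
    "probability_link"
  ],
  "title": "diabrisk score specification",
  "type": "object",
  "$schema": "https://json-schema.org/draft/2020-12/schema"
}
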