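{
  "$defs": {
    "CostEstimate": {
      "description": "A money amount (2020 USD) with a low/high sensitivity range.",
      "properties": {
        "mean": {
          "minimum": 0.0,
          "title": "Mean",
          "type": "number"
        },
        "low": {
          "anyOf": [
            {
              "type": "number"
            },
            {
              "type": "null"
            }
          ],
          "default": null,
          "title": "Low"
        },
        "high": {
          "anyOf": [
            {
              "type": "number"
            },
            {
              "type": "null"
            }
          ],
          "default": null,
          "title": "High"
        }
      },
      "required": [
        "mean"
      ],
      "title": "CostEstimate",
      "type": "object"
    },
    "EconomicInputs": {
      "description": "Utilities, costs, discounting, horizon and willingness to pay.",
      "properties": {
        "utilities": {
          "additionalProperties": {
            "$ref": "#/$defs/ProbEstimate"
          },
          "propertyNames": {
            "$ref": "#/$defs/HealthState"
          },
          "title": "Utilities",
          "type": "object"
        },
        "aki_episode_cost": {
          "$ref": "#/$defs/CostEstimate"
        },
        "annual_state_costs": {
          "additionalProperties": {
            "$ref": "#/$defs/CostEstimate"
          },
          "propertyNames": {
            "$ref": "#/$defs/HealthState"
          },
          "title": "Annual State Costs",
          "type": "object"
        },
        "discount_rate": {
          "minimum": 0.0,
          "title": "Discount Rate",
          "type": "number"
        },
        "horizon_years": {
          "minimum": 1,
          "title": "Horizon Years",
          "type": "integer"
        },
        "wtp": {
          "exclusiveMinimum": 0.0,
          "title": "Wtp",
          "type": "number"
        }
      },
      "required": [
        "utilities",
        "aki_episode_cost",
        "annual_state_costs",
        "discount_rate",
        "horizon_years",
        "wtp"
      ],
      "title": "EconomicInputs",
      "type": "object"
    },
    "HealthState": {
      "enum": [
        "NORMAL",
        "CKD",
        "ESRD",
        "DEATH"
      ],
      "title": "HealthState",
      "type": "string"
    },
    "ProbEstimate": {
      "description": "A probability with a (possibly degenerate) 95% confidence interval.",
      "properties": {
        "mean": {
          "title": "Mean",
          "type": "number"
        },
        "ci_low": {
          "anyOf": [
            {
              "type": "number"
            },
            {
              "type": "null"
            }
          ],
          "default": null,
          "title": "Ci Low"
        },
        "ci_high": {
          "anyOf": [
            {
              "type": "number"
            },
            {
              "type": "null"
            }
          ],
          "default": null,
          "title": "Ci High"
        }
      },
      "required": [
        "mean"
      ],
      "title": "ProbEstimate",
      "type": "object"
    },
    "StrategySpec": {
      "description": "One implementation strategy: AKI probability and upfront cost.",
      "properties": {
        "name": {
          "enum": [
            "assistance",
            "assistance_surveillance",
            "collaborative",
            "collaborative_surveillance"
          ],
          "title": "Name",
          "type": "string"
        },
        "p_aki": {
          "$ref": "#/$defs/ProbEstimate"
        },
        "upfront_cost": {
          "$ref": "#/$defs/CostEstimate"
        }
      },
      "required": [
        "name",
        "p_aki",
        "upfront_cost"
      ],
      "title": "StrategySpec",
      "type": "object"
    },
    "TransitionTables": {
      "description": "30-day dispositions by AKI status and annual transitions by history.\n\n``thirty_day[status][state]`` is the probability of occupying ``state``\nat day 30 given AKI status; each row must sum to one within\n``THIRTY_DAY_SUM_TOL`` and is renormalized proportionally at load.\n\n``annual[hist][origin][dest]`` are yearly exit probabilities; the stay\nprobability is the residual and must be non-negative.  Backward\ntransitions (e.g. CKD to normal) are structurally absent.",
      "properties": {
        "thirty_day": {
          "additionalProperties": {
            "additionalProperties": {
              "$ref": "#/$defs/ProbEstimate"
            },
            "propertyNames": {
              "$ref": "#/$defs/HealthState"
            },
            "type": "object"
          },
          "propertyNames": {
            "enum": [
              "aki",
              "no_aki"
            ]
          },
          "title": "Thirty Day",
          "type": "object"
        },
        "annual": {
          "additionalProperties": {
            "additionalProperties": {
              "additionalProperties": {
                "$ref": "#/$defs/ProbEstimate"
              },
              "propertyNames": {
                "$ref": "#/$defs/HealthState"
              },
              "type": "object"
            },
            "propertyNames": {
              "$ref": "#/$defs/HealthState"
            },
            "type": "object"
          },
          "propertyNames": {
            "enum": [
              "after_aki",
              "no_aki"
            ]
          },
          "title": "Annual",
          "type": "object"
        }
      },
      "required": [
        "thirty_day",
        "annual"
      ],
      "title": "TransitionTables",
      "type": "object"
    }
  },
  "description": "The full declarative model: strategies, transitions, economics.",
  "properties": {
    "strategies": {
      "additionalProperties": {
        "$ref": "#/$defs/StrategySpec"
      },
      "title": "Strategies",
      "type": "object"
    },
    "transitions": {
      "$ref": "#/$defs/TransitionTables"
    },
    "economics": {
      "$ref": "#/$defs/EconomicInputs"
    }
  },
  "required": [
    "strategies",
    "transitions",
    "economics"
  ],
  "title": "ModelBundle",
  "type": "object"
}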