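{
  "$defs": {
    "MCSystemEntry": {
      "properties": {
        "median": {
          "title": "Median",
          "type": "number"
        },
        "p2_5": {
          "title": "P2 5",
          "type": "number"
        },
        "p97_5": {
          "title": "P97 5",
          "type": "number"
        }
      },
      "required": [
        "median",
        "p2_5",
        "p97_5"
      ],
      "title": "MCSystemEntry",
      "type": "object"
    },
    "Manifest": {
      "properties": {
        "allocation": {
          "title": "Allocation",
          "type": "string"
        },
        "cattle_share": {
          "title": "Cattle Share",
          "type": "number"
        },
        "config_hash": {
          "title": "Config Hash",
          "type": "string"
        },
        "gwp": {
          "title": "Gwp",
          "type": "string"
        },
        "package": {
          "default": "herdlca",
          "title": "Package",
          "type": "string"
        },
        "seed": {
          "anyOf": [
            {
              "type": "integer"
            },
            {
              "type": "null"
            }
          ],
          "default": null,
          "title": "Seed"
        },
        "version": {
          "title": "Version",
          "type": "string"
        }
      },
      "required": [
        "version",
        "config_hash",
        "gwp",
        "allocation",
        "cattle_share"
      ],
      "title": "Manifest",
      "type": "object"
    },
    "RepresentativeEntry": {
      "properties": {
        "bias": {
          "title": "Bias",
          "type": "number"
        },
        "mean_individual_ei": {
          "title": "Mean Individual Ei",
          "type": "number"
        },
        "representative_ei": {
          "title": "Representative Ei",
          "type": "number"
        }
      },
      "required": [
        "mean_individual_ei",
        "representative_ei",
        "bias"
      ],
      "title": "RepresentativeEntry",
      "type": "object"
    },
    "SystemSummary": {
      "properties": {
        "best_ei": {
          "title": "Best Ei",
          "type": "number"
        },
        "mean_adg": {
          "title": "Mean Adg",
          "type": "number"
        },
        "mean_ei": {
          "title": "Mean Ei",
          "type": "number"
        },
        "n": {
          "title": "N",
          "type": "integer"
        },
        "percent_spread": {
          "title": "Percent Spread",
          "type": "number"
        },
        "worst_ei": {
          "title": "Worst Ei",
          "type": "number"
        }
      },
      "required": [
        "n",
        "mean_ei",
        "best_ei",
        "worst_ei",
        "percent_spread",
        "mean_adg"
      ],
      "title": "SystemSummary",
      "type": "object"
    },
    "TestStat": {
      "properties": {
        "pvalue": {
          "title": "Pvalue",
          "type": "number"
        },
        "statistic": {
          "title": "Statistic",
          "type": "number"
        }
      },
      "required": [
        "statistic",
        "pvalue"
      ],
      "title": "TestStat",
      "type": "object"
    }
  },
  "description": "Top-level pipeline report.",
  "properties": {
    "anova": {
      "additionalProperties": {
        "$ref": "#/$defs/TestStat"
      },
      "title": "Anova",
      "type": "object"
    },
    "correlations": {
      "additionalProperties": {
        "$ref": "#/$defs/TestStat"
      },
      "title": "Correlations",
      "type": "object"
    },
    "distributions": {
      "additionalProperties": {
        "additionalProperties": {
          "additionalProperties": true,
          "type": "object"
        },
        "type": "object"
      },
      "title": "Distributions",
      "type": "object"
    },
    "manifest": {
      "$ref": "#/$defs/Manifest"
    },
    "mc_pairwise": {
      "anyOf": [
        {
          "additionalProperties": {
            "$ref": "#/$defs/TestStat"
          },
          "type": "object"
        },
        {
          "type": "null"
        }
      ],
      "default": null,
      "title": "Mc Pairwise"
    },
    "monte_carlo": {
      "anyOf": [
        {
          "additionalProperties": {
            "$ref": "#/$defs/MCSystemEntry"
          },
          "type": "object"
        },
        {
          "type": "null"
        }
      ],
      "default": null,
      "title": "Monte Carlo"
    },
    "pairwise_ei": {
      "additionalProperties": {
        "$ref": "#/$defs/TestStat"
      },
      "title": "Pairwise Ei",
      "type": "object"
    },
    "per_system": {
      "additionalProperties": {
        "$ref": "#/$defs/SystemSummary"
      },
      "title": "Per System",
      "type": "object"
    },
    "representative": {
      "additionalProperties": {
        "$ref": "#/$defs/RepresentativeEntry"
      },
      "title": "Representative",
      "type": "object"
    },
    "sex_contrasts": {
      "additionalProperties": {
        "additionalProperties": {
          "additionalProperties": {
            "type": "number"
          },
          "type": "object"
        },
        "type": "object"
      },
      "title": "Sex Contrasts",
      "type": "object"
    },
    "warnings": {
      "items": {
        "type": "string"
      },
      "title": "Warnings",
      "type": "array"
    }
  },
  "required": [
    "manifest",
    "per_system",
    "representative"
  ],
  "title": "ReportDocument",
  "type": "object"
}
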