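{
  "$defs": {
    "FlowResultModel": {
      "properties": {
        "forward_volume_ml": {
          "title": "Forward Volume Ml",
          "type": "number"
        },
        "regurgitant_volumes_ml": {
          "additionalProperties": {
            "type": "number"
          },
          "title": "Regurgitant Volumes Ml",
          "type": "object"
        },
        "total_regurgitant_ml": {
          "title": "Total Regurgitant Ml",
          "type": "number"
        },
        "effective_forward_ml": {
          "title": "Effective Forward Ml",
          "type": "number"
        },
        "regurgitant_fraction_pct": {
          "title": "Regurgitant Fraction Pct",
          "type": "number"
        },
        "aortic_volume_ml": {
          "title": "Aortic Volume Ml",
          "type": "number"
        },
        "internal_validation_diff_ml": {
          "title": "Internal Validation Diff Ml",
          "type": "number"
        },
        "per_phase_rates": {
          "additionalProperties": {
            "additionalProperties": {
              "items": {
                "type": "number"
              },
              "type": "array"
            },
            "type": "object"
          },
          "title": "Per Phase Rates",
          "type": "object"
        }
      },
      "required": [
        "forward_volume_ml",
        "regurgitant_volumes_ml",
        "total_regurgitant_ml",
        "effective_forward_ml",
        "regurgitant_fraction_pct",
        "aortic_volume_ml",
        "internal_validation_diff_ml"
      ],
      "title": "FlowResultModel",
      "type": "object"
    },
    "GroundTruthDeltas": {
      "description": "Measured minus true, present only for phantom input.",
      "properties": {
        "forward_volume_ml": {
          "title": "Forward Volume Ml",
          "type": "number"
        },
        "total_regurgitant_ml": {
          "title": "Total Regurgitant Ml",
          "type": "number"
        },
        "regurgitant_fraction_pct": {
          "title": "Regurgitant Fraction Pct",
          "type": "number"
        },
        "aortic_volume_ml": {
          "title": "Aortic Volume Ml",
          "type": "number"
        },
        "internal_validation_diff_ml": {
          "title": "Internal Validation Diff Ml",
          "type": "number"
        }
      },
      "required": [
        "forward_volume_ml",
        "total_regurgitant_ml",
        "regurgitant_fraction_pct",
        "aortic_volume_ml",
        "internal_validation_diff_ml"
      ],
      "title": "GroundTruthDeltas",
      "type": "object"
    },
    "JetCharacterizationModel": {
      "properties": {
        "label": {
          "title": "Label",
          "type": "string"
        },
        "per_phase_angles_deg": {
          "additionalProperties": {
            "additionalProperties": {
              "type": "number"
            },
            "type": "object"
          },
          "title": "Per Phase Angles Deg",
          "type": "object"
        },
        "min_angle_deg": {
          "additionalProperties": {
            "type": "number"
          },
          "title": "Min Angle Deg",
          "type": "object"
        },
        "max_angle_deg": {
          "additionalProperties": {
            "type": "number"
          },
          "title": "Max Angle Deg",
          "type": "object"
        },
        "angle_difference_deg": {
          "additionalProperties": {
            "type": "number"
          },
          "title": "Angle Difference Deg",
          "type": "object"
        },
        "circularity_index": {
          "title": "Circularity Index",
          "type": "number"
        },
        "peak_phase": {
          "title": "Peak Phase",
          "type": "integer"
        }
      },
      "required": [
        "label",
        "per_phase_angles_deg",
        "min_angle_deg",
        "max_angle_deg",
        "angle_difference_deg",
        "circularity_index",
        "peak_phase"
      ],
      "title": "JetCharacterizationModel",
      "type": "object"
    },
    "Provenance": {
      "properties": {
        "config_hash": {
          "title": "Config Hash",
          "type": "string"
        },
        "seed": {
          "title": "Seed",
          "type": "integer"
        },
        "version": {
          "title": "Version",
          "type": "string"
        }
      },
      "required": [
        "config_hash",
        "seed",
        "version"
      ],
      "title": "Provenance",
      "type": "object"
    }
  },
  "properties": {
    "flow": {
      "$ref": "#/$defs/FlowResultModel"
    },
    "jets": {
      "items": {
        "$ref": "#/$defs/JetCharacterizationModel"
      },
      "title": "Jets",
      "type": "array"
    },
    "volumetry": {
      "anyOf": [
        {
          "additionalProperties": true,
          "type": "object"
        },
        {
          "type": "null"
        }
      ],
      "default": null,
      "title": "Volumetry"
    },
    "agreement": {
      "anyOf": [
        {
          "additionalProperties": true,
          "type": "object"
        },
        {
          "type": "null"
        }
      ],
      "default": null,
      "title": "Agreement"
    },
    "ground_truth_deltas": {
      "anyOf": [
        {
          "$ref": "#/$defs/GroundTruthDeltas"
        },
        {
          "type": "null"
        }
      ],
      "default": null
    },
    "provenance": {
      "$ref": "#/$defs/Provenance"
    }
  },
  "required": [
    "flow",
    "provenance"
  ],
  "title": "SubjectReport",
  "type": "object"
}
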