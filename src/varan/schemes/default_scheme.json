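{
  "name": "default-ensemble-filter",
  "version": "1.0",
  "categories": [
    {
      "name": "Calling confidence",
      "entries": [
        {
          "id": "few_callers",
          "label": "Reported by fewer callers than required",
          "active": true,
          "artifact_weight": 1.0,
          "polymorphism_weight": 0.0,
          "condition": { "expr": "x(\"caller_count\") < th(\"minCallers\")" }
        },
        {
          "id": "low_vaf",
          "label": "Variant allele frequency below noise floor",
          "active": true,
          "artifact_weight": 1.0,
          "polymorphism_weight": 0.0,
          "condition": { "expr": "x(\"VAF\") < th(\"minVAF\")" }
        },
        {
          "id": "low_base_quality",
          "label": "Mean base quality of supporting reads too low",
          "active": true,
          "artifact_weight": 1.0,
          "polymorphism_weight": 0.0,
          "condition": { "expr": "x(\"MBQ\") < th(\"minBQ\")" }
        }
      ]
    },
    {
      "name": "Database evidence",
      "entries": [
        {
          "id": "common_polymorphism",
          "label": "Known population variant without clinical flag",
          "active": true,
          "artifact_weight": 0.0,
          "polymorphism_weight": 1.0,
          "condition": {
            "op": "AND",
            "children": [
              { "expr": "not isEmpty(x(\"dbsnp.id\"))" },
              { "expr": "isEmpty(x(\"dbsnp.PM\"))" },
              { "expr": "x(\"popfreq.AF\") >= th(\"maxAF\")" },
              {
                "op": "OR",
                "children": [
                  { "expr": "isEmpty(x(\"cosmic.occurrence\"))" },
                  { "expr": "x(\"cosmic.occurrence\") < th(\"minCosmic\")" }
                ]
              }
            ]
          }
        },
        {
          "id": "benign_clinsig",
          "label": "Annotated benign or likely benign",
          "active": true,
          "artifact_weight": 0.0,
          "polymorphism_weight": 1.0,
          "condition": { "expr": "stringContains(x(\"clinsig.significance\"), \"benign\")" }
        }
      ]
    }
  ],
  "thresholds": {
    "minCallers": {
      "default": 2,
      "min": 1,
      "max": 8,
      "description": "Minimum number of callers that must report a variant"
    },
    "minVAF": {
      "default": 0.02,
      "min": 0.0,
      "max": 1.0,
      "description": "Minimum variant allele frequency"
    },
    "minBQ": {
      "default": 20,
      "min": 0,
      "max": 45,
      "description": "Minimum mean base quality of supporting reads"
    },
    "maxAF": {
      "default": 0.01,
      "min": 0.0,
      "max": 1.0,
      "description": "Population allele frequency above which an unflagged database variant is treated as polymorphism"
    },
    "minCosmic": {
      "default": 5,
      "min": 0,
      "max": 1000,
      "description": "Somatic-database occurrence count that rescues a variant from the polymorphism rule"
    }
  },
  "cutoffs": {
    "artifact_cutoff": 1.0,
    "polymorphism_cutoff": 1.0
  }
}
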