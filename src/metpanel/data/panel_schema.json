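{
  "$schema": "https://json-schema.org/draft/2020-12/schema",
  "title": "metpanel panel configuration",
  "description": "Schema of the YAML/JSON panel config consumed by metpanel.panel_registry.load_panel: gene-disease entries, biochemical assays, and numeric thresholds.",
  "type": "object",
  "required": ["genes", "assays"],
  "properties": {
    "genes": {
      "type": "array",
      "minItems": 1,
      "items": {
        "type": "object",
        "required": ["symbol", "transcript", "exon_count", "inheritance", "disease_id", "disease_name", "category"],
        "properties": {
          "symbol": {"type": "string"},
          "transcript": {"type": "string"},
          "exon_count": {"type": "integer", "minimum": 1},
          "inheritance": {"enum": ["AR", "AD", "XL"]},
          "disease_id": {"type": "string"},
          "disease_name": {"type": "string"},
          "category": {
            "enum": ["lysosomal", "carbohydrate", "amino_acid_peptide",
                     "organic_acid", "fatty_acid_oxidation", "urea_cycle",
                     "metal_metabolism", "peroxisomal", "mitochondrial_energy",
                     "glycosylation", "purine_pyrimidine", "neurotransmitter",
                     "vitamin_cofactor", "lipid_lipoprotein", "steroid",
                     "bile_acid_liver", "porphyrin_heme", "other_metabolic"]
          },
          "treatable": {"type": "boolean", "default": false},
          "assay_ids": {"type": "array", "items": {"type": "string"}, "default": []},
          "chrom": {"type": "string", "default": "chr1"},
          "female_het_reportable": {"type": "boolean", "default": false},
          "lof_mechanism": {"type": "boolean", "default": true},
          "placeholder": {"type": "boolean", "default": false}
        }
      }
    },
    "assays": {
      "type": "array",
      "items": {
        "type": "object",
        "required": ["assay_id", "kind", "analyte", "pathologic_direction", "reference_low", "reference_high", "units"],
        "properties": {
          "assay_id": {"type": "string"},
          "kind": {"enum": ["enzyme_activity", "biomarker"]},
          "analyte": {"type": "string"},
          "pathologic_direction": {"enum": ["below_range", "above_range"]},
          "reference_low": {"type": "number"},
          "reference_high": {"type": "number"},
          "units": {"type": "string"}
        }
      }
    },
    "thresholds": {
      "type": "object",
      "properties": {
        "maf_snv": {"type": "number", "default": 0.01},
        "maf_cnv": {"type": "number", "default": 0.02},
        "splice_score_min": {"type": "number", "default": 0.6},
        "het_cnv_min_exons": {"type": "integer", "default": 3},
        "qc_min_coverage_fraction": {"type": "number", "default": 0.995},
        "qc_min_depth": {"type": "integer", "default": 20},
        "healthy_cohort_size": {"type": "integer", "default": 24000},
        "grey_zone": {"type": "number", "default": 0.10},
        "c2_literal": {"type": "boolean", "default": false},
        "reflex_on_carrier": {"type": "boolean", "default": false}
      }
    }
  }
}
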