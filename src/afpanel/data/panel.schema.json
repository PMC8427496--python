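{
 "$defs": {
  "GeneRecord": {
   "description": "One panel gene with syndrome, inheritance and reporting metadata.",
   "properties": {
    "symbol": {
     "title": "Symbol",
     "type": "string"
    },
    "panels": {
     "items": {
      "enum": [
       "arrhythmia",
       "cardiomyopathy"
      ],
      "type": "string"
     },
     "title": "Panels",
     "type": "array"
    },
    "syndromes": {
     "items": {
      "enum": [
       "AC_ARVC",
       "Brugada",
       "CPVT",
       "DCM",
       "HCM",
       "LQTS",
       "other"
      ],
      "type": "string"
     },
     "title": "Syndromes",
     "type": "array"
    },
    "clingen_level": {
     "additionalProperties": {
      "enum": [
       "definitive",
       "strong",
       "moderate",
       "limited",
       "disputed",
       "none"
      ],
      "type": "string"
     },
     "title": "Clingen Level",
     "type": "object"
    },
    "inheritance_modes": {
     "items": {
      "enum": [
       "AD",
       "AR",
       "XLD",
       "XLR"
      ],
      "type": "string"
     },
     "title": "Inheritance Modes",
     "type": "array"
    },
    "lof_mechanism": {
     "default": true,
     "title": "Lof Mechanism",
     "type": "boolean"
    },
    "transcript_length_kbp": {
     "exclusiveMinimum": 0,
     "title": "Transcript Length Kbp",
     "type": "number"
    },
    "reporting_rule": {
     "default": "all_rare",
     "enum": [
      "all_rare",
      "lof_only"
     ],
     "title": "Reporting Rule",
     "type": "string"
    },
    "provenance": {
     "default": "inferred",
     "enum": [
      "stated",
      "inferred",
      "provisional"
     ],
     "title": "Provenance",
     "type": "string"
    }
   },
   "required": [
    "symbol",
    "panels",
    "inheritance_modes",
    "transcript_length_kbp"
   ],
   "title": "GeneRecord",
   "type": "object"
  }
 },
 "description": "A validated gene panel.",
 "properties": {
  "name": {
   "title": "Name",
   "type": "string"
  },
  "version_date": {
   "format": "date",
   "title": "Version Date",
   "type": "string"
  },
  "genes": {
   "items": {
    "$ref": "#/$defs/GeneRecord"
   },
   "title": "Genes",
   "type": "array"
  }
 },
 "required": [
  "name",
  "version_date",
  "genes"
 ],
 "title": "PanelConfig",
 "type": "object"
}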