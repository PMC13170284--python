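{
  "description": "Synthetic stand-in code sets. The study's supplementary medication and ICD-10 lists are not publicly deposited; these editable defaults carry the same structure (statin medication names, diabetes and exclusion-diagnosis ICD-10 prefixes) so that the classification logic is fully exercised. Replace with site-specific lists for real data.",
  "synthetic": true,
  "statin_medications": [
    "atorvastatin",
    "rosuvastatin",
    "simvastatin",
    "pravastatin",
    "lovastatin",
    "fluvastatin",
    "pitavastatin"
  ],
  "diabetes_icd10_prefixes": ["E11"],
  "exclusion_icd10_prefixes": {
    "hepatitis": ["B15", "B16", "B17", "B18", "B19", "K75.9"],
    "cirrhosis": ["K70.3", "K74.6"],
    "esrd": ["N18.6"],
    "ckd": ["N18.1", "N18.2", "N18.3", "N18.4", "N18.5", "N18.9"]
  }
}
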