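{
  "_comment": "High-resolution product-ion library entry for 5-HETE ([M-H]- m/z 319.2). Fragment m/z values are the published quantifier/qualifier ions; relative intensities are SYNTHETIC placeholders (the published spectrum image is not machine-readable) chosen so the quantifier is the base peak.",
  "entries": [
    {
      "analyte_id": "5-HETE",
      "precursor_mz": 319.2275,
      "fragments": [
        {"mz": 115.0395, "relative_intensity": 1.0, "annotation": "C5H7O3- quantifier", "quantifier": true},
        {"mz": 257.2279, "relative_intensity": 0.35, "annotation": "[M-H-H2O-CO2]-", "quantifier": false},
        {"mz": 203.1805, "relative_intensity": 0.3, "annotation": "C14H19O-", "quantifier": false},
        {"mz": 59.0151, "relative_intensity": 0.25, "annotation": "C2H3O2-", "quantifier": false}
      ]
    }
  ]
}
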