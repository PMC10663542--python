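{
  "comment": "van der Waals radii in Angstrom, keyed by element symbol (Bondi 1964 with common biomolecular extensions); 'default' is used for unlisted elements",
  "default": 1.7,
  "H": 1.2,
  "C": 1.7,
  "N": 1.55,
  "O": 1.52,
  "S": 1.8,
  "P": 1.8,
  "F": 1.47,
  "CL": 1.75,
  "BR": 1.85,
  "I": 1.98,
  "NA": 2.27,
  "K": 2.75,
  "MG": 1.73,
  "CA": 2.31,
  "ZN": 1.39,
  "FE": 1.4,
  "CU": 1.4,
  "MN": 1.4,
  "CD": 1.58,
  "SE": 1.9
}
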