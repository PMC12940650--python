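{
  "name": "toy",
  "sites": [
    {"name": "site1", "residues": ["A", "B", "C", "D"]},
    {"name": "site2", "residues": ["A", "B", "C", "D"]},
    {"name": "site3", "residues": ["A", "B", "C"]}
  ]
}
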