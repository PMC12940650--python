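{
  "name": "antihiv-nucleoside",
  "sites": [
    {"name": "site1", "residues": ["A", "B", "C", "D", "E", "F", "G", "H"]},
    {"name": "site2", "residues": ["A", "B", "C"]},
    {"name": "site3", "residues": ["A", "B", "C", "D", "E"]},
    {"name": "site4", "residues": ["A", "B", "C", "D", "E", "F", "G", "H", "I", "J", "K", "L", "M", "N", "O", "P", "Q", "R", "S", "T", "U", "V"]},
    {"name": "site5", "residues": ["A", "B"]},
    {"name": "site6", "residues": ["A", "B", "C", "D", "E", "F", "G", "H", "I", "J", "K", "L"]},
    {"name": "site7", "residues": ["A", "B", "C", "D", "E"]},
    {"name": "site8", "residues": ["A", "B", "C", "D", "E", "F", "G", "H", "I", "J", "K", "L", "M", "N", "O"]},
    {"name": "site9", "residues": ["A", "B", "C", "D", "E", "F", "G", "H", "I", "J", "K", "L", "M", "N", "O"]}
  ]
}
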