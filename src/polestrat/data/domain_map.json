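{
  "description": "POLE (catalytic subunit, 2286 aa) domain architecture. Lobe tier tiles the protein: N-terminal lobe (NTL, 1-1183) and C-terminal lobe (CTL, 1184-2286). Fine tier: exonuclease domain (ExoD) and polymerase subdomains; boundaries are configurable defaults chosen to contain the 20 ExoD driver residues (275-465) and standard subdomain assignments (e.g. 680 palm, 1125 thumb).",
  "protein_length": 2286,
  "lobes": [
    {"name": "NTL", "start": 1, "end": 1183},
    {"name": "CTL", "start": 1184, "end": 2286}
  ],
  "domains": [
    {"name": "NTD", "start": 1, "end": 267},
    {"name": "ExoD", "start": 268, "end": 471},
    {"name": "palm", "start": 528, "end": 950},
    {"name": "fingers", "start": 951, "end": 1075},
    {"name": "thumb", "start": 1076, "end": 1183},
    {"name": "CTD", "start": 1184, "end": 2286}
  ]
}
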