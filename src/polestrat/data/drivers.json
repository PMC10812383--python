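{
  "description": "Curated POLE exonuclease-domain proofreading driver alleles (shorthand; slash-separated alternates expand to one allele each, 20 total).",
  "drivers": [
    "D275G",
    "P286R",
    "S297F/Y",
    "F367C/L/V",
    "V411L",
    "L424F",
    "P436R/S/Y",
    "M444K/L",
    "A456P",
    "S459F/Y",
    "S461L/P",
    "A465V"
  ]
}
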