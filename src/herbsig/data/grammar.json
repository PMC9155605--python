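{
  "scaffolds": [
    "c1ccccc1",
    "c1ccncc1",
    "c1ccoc1",
    "c1ccsc1",
    "C1CCCCC1",
    "C1CCCC1",
    "C1CCNCC1",
    "CCCC",
    "CCCCC",
    "CCOCC"
  ],
  "decorators": [
    "C",
    "CC",
    "CCC",
    "C(C)C",
    "O",
    "N",
    "F",
    "Cl",
    "Br",
    "OC",
    "CO",
    "C(=O)O",
    "C(=O)C",
    "C#N",
    "C(F)(F)F",
    "N(C)C",
    "[N+](=O)[O-]",
    "S"
  ]
}
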