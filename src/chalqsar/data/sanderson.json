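{
  "comment": "Sanderson electronegativities used to weight the Barysz distance matrix.",
  "values": {
    "H": 2.592,
    "B": 2.275,
    "C": 2.746,
    "N": 3.194,
    "O": 3.654,
    "F": 4.0,
    "Si": 2.138,
    "P": 2.515,
    "S": 2.957,
    "Cl": 3.475,
    "Br": 3.219,
    "I": 2.778
  }
}
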