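{
 "name": "kyte_doolittle_1982",
 "values": {
  "A": 1.8,
  "C": 2.5,
  "D": -3.5,
  "E": -3.5,
  "F": 2.8,
  "G": -0.4,
  "H": -3.2,
  "I": 4.5,
  "K": -3.9,
  "L": 3.8,
  "M": 1.9,
  "N": -3.5,
  "P": -1.6,
  "Q": -3.5,
  "R": -4.5,
  "S": -0.8,
  "T": -0.7,
  "V": 4.2,
  "W": -0.9,
  "Y": -1.3
 }
}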