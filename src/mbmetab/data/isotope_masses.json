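{
  "version": "1.0",
  "source": "most-abundant-isotope monoisotopic masses, CODATA/AME2020 rounded to 1e-9 Da",
  "electron_mass": 0.000548579909,
  "masses": {
    "H": 1.007825032,
    "C": 12.0,
    "N": 14.003074005,
    "O": 15.994914620,
    "Na": 22.989769282,
    "P": 30.973761998,
    "S": 31.972071174,
    "K": 38.963706487
  }
}
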