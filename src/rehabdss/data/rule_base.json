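{
  "version": 1,
  "description": "Cycle-plan inference rule base: rehabilitation stage (Brunnstrom stage + muscle tone grade) -> training weeks, mode and strength level for the two main daily stages. Warm-up and relaxation phases are always passive at the lowest difficulty (F1).",
  "rules": [
    {"brunnstrom": "II", "tones": ["0"], "weeks": 1, "mode": "passive", "strength_level": "F2"},
    {"brunnstrom": "II", "tones": ["1", "1+", "2"], "weeks": 1, "mode": "passive", "strength_level": "F3"},
    {"brunnstrom": "III", "tones": ["3", "4"], "weeks": 2, "mode": "assisted", "strength_level": "F5"},
    {"brunnstrom": "III", "tones": ["1", "1+", "2"], "weeks": 2, "mode": "assisted", "strength_level": "F2"},
    {"brunnstrom": "IV", "tones": ["1", "1+", "2"], "weeks": 5, "mode": "resisted", "strength_level": "F2"},
    {"brunnstrom": "V", "tones": ["1", "1+", "2"], "weeks": 8, "mode": "resisted", "strength_level": "F3"}
  ]
}
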