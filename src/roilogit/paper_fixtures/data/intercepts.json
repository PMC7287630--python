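{
  "Day1": 0.36,
  "Day2": 1.87,
  "Subgroup-Day1": {"START": -0.3254, "STOPP": -0.4127, "POTS": 0.3718},
  "Subgroup-Day2": {"START": -0.1666, "STOPP": -0.0894, "POTS": 0.0274}
}
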