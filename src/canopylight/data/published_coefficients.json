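{
  "a0": 3102448,
  "a1": -61307,
  "a2": -8220,
  "a3": -515,
  "a4": 235,
  "a5": 883,
  "a6": 16,
  "a7": -2301,
  "a8": 6,
  "a9": -0.334
}
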