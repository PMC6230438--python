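{
  "comment": "Optimised single-limb CPG parameters for cat overground walking",
  "x01": -0.0007,
  "x02": 2.4256,
  "g1": 0.6203,
  "g2": 0.4882,
  "r_leak": -0.0094
}
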