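{
  "comment": "Printed speed-to-drive regression, cycle-duration power law and constant swing approximation for cat walking",
  "u_offset": 0.1272,
  "u_scale": 0.2357,
  "emp_coeff": 0.5445,
  "emp_exp": -0.5925,
  "swing_const": 0.25
}
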