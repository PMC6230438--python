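{
  "comment": "Curved-walk demonstration schedules: five steps at a constant mean speed with the interlimb speed differential ramping linearly from 0 to dV_max",
  "n_steps": 5,
  "dV_max_mps": 0.2,
  "mean_speeds_mps": [0.5, 1.0, 2.0],
  "step_width_m": 0.15
}
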