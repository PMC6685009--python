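# Two-compartment model with a known external input u(t) entering through
# an unknown gain b.  Measured output: the first compartment.
name: c2m_original
states: [x1, x2]
odes:
  x1: -(k1e + k12)*x1 + k21*x2 + b*u
  x2: k12*x1 - k21*x2
outputs: [x1]
known_inputs: [u]
unknown_inputs: []
parameters: [k1e, k12, k21, b]
constants: {}
init:
  x1: 1.0
  x2: "?"
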