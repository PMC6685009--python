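# Two-compartment model with the unmeasured excitation folded into a single
# unknown input w(t) = b*u(t) (only the product of gain and signal is
# determinable when both are unknown).
name: c2m
states: [x1, x2]
odes:
  x1: -(k1e + k12)*x1 + k21*x2 + w
  x2: k12*x1 - k21*x2
outputs: [x1]
known_inputs: []
unknown_inputs: [w]
parameters: [k1e, k12, k21]
constants: {}
init:
  x1: 1.0
  x2: "?"
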