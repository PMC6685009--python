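# Toggle switch with the unobservable induction terms absorbed into unknown
# inputs w1 = (aTc/theta_aTc)**n_aTc and w2 = (IPTG/theta_IPTG)**n_IPTG,
# leaving six unknown parameters.
name: toggle_switch_reformulated
states: [x1, x2]
odes:
  x1: k01 + k1/(1 + (x2/(1 + w1))**n_TetR) - x1
  x2: k02 + k2/(1 + (x1/(1 + w2))**n_LacI) - x2
outputs: [x1, x2]
known_inputs: []
unknown_inputs: [w1, w2]
parameters: [k01, k1, n_TetR, k02, k2, n_LacI]
constants: {}
init:
  x1: 1.2
  x2: 0.8
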