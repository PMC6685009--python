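# Genetic toggle switch: two mutually repressing genes, induced by the
# (known) inducer molecules aTc and IPTG.  States are dimensionless protein
# levels; both are measured.
name: toggle_switch
states: [x1, x2]
odes:
  x1: k01 + k1/(1 + (x2/(1 + (aTc/theta_aTc)**n_aTc))**n_TetR) - x1
  x2: k02 + k2/(1 + (x1/(1 + (IPTG/theta_IPTG)**n_IPTG))**n_LacI) - x2
outputs: [x1, x2]
known_inputs: [aTc, IPTG]
unknown_inputs: []
parameters: [k01, k1, theta_aTc, n_aTc, n_TetR, k02, k2, theta_IPTG, n_IPTG, n_LacI]
constants: {}
init:
  x1: 1.2
  x2: 0.8
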