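# Within-host HIV infection dynamics: uninfected cells T_U, infected cells
# T_I and viral load V, with a time-varying, unknown infection rate eta(t).
# Measured outputs: viral load and total cell count.  Units are rescaled so
# that states and rates are of order 0.1-10.
name: hiv
states: [T_U, T_I, V]
odes:
  T_U: lam - rho*T_U - eta*T_U*V
  T_I: eta*T_U*V - delta*T_I
  V: N*delta*T_I - c*V
outputs: [V, T_U + T_I]
known_inputs: []
unknown_inputs: [eta]
parameters: [lam, rho, delta, N, c]
constants: {}
init:
  T_U: 10.0
  T_I: 0.5
  V: 2.0
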