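# Imposition of selection on the oscillatory phenotype from the neutral
# non-selecting equilibrium.
run: trajectory-impose
model: clock
mutation: {lambda: 0.6, delta: 1.85, pi: 6.0, m: 1.0e-7}
fitness: {mode: neutral, mu7_star: 1.00006}
horizon: 1.0e+9
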