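# Protein-burden fitness spectrum at m = 1e-7: entropy-selection balance
# concentrates the population on phenotype 11.
run: equilibrium
model: clock
mutation: {lambda: 0.6, delta: 1.85, pi: 6.0, m: 1.0e-7}
fitness: {mode: burden_printed, mu7_star: 1.0}
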