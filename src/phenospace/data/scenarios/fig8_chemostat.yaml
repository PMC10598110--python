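# Deterministic expected counts after growth from one founder cell of the
# oscillatory phenotype to 1e13 cells.
run: chemostat
model: clock
mutation: {lambda: 0.6, delta: 1.85, pi: 6.0, m: 1.0e-7}
fitness: {mode: neutral}
founder: 7
target_total: 1.0e+13
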