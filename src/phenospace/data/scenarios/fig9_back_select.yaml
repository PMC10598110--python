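# Back-calculate the selection strength needed for a 60% oscillatory
# aggregate class at equilibrium.
run: back-select
model: clock
mutation: {lambda: 0.6, delta: 1.85, pi: 6.0, m: 1.0e-7}
fitness: {mode: burden_printed}
target_fraction: 0.60
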