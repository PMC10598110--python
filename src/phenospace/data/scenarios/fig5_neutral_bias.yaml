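# Neutral fitness, size scale and directional bias active:
# equilibrium with an entropy gradient of ~4-5 decades.
run: equilibrium
model: clock
mutation: {lambda: 0.6, delta: 1.85, pi: 6.0, m: 1.0e-7}
fitness: {mode: neutral, mu7_star: 1.0}
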