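# Removal of selection: relaxation from the selecting equilibrium back to
# the non-selecting one (orders of magnitude slower than imposition).
run: trajectory-remove
model: clock
mutation: {lambda: 0.6, delta: 1.85, pi: 6.0, m: 1.0e-7}
fitness: {mode: neutral, mu7_star: 1.00006}
horizon: 3.0e+10
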