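# Fit (lambda, delta) to the packaged LAC tolerance proportions.
run: fit-bias
model: clock
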