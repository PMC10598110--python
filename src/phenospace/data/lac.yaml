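# Mutant-class proportions for repressor DNA-binding substitutions,
# measured at time zero (tolerant = inducible wild type).
source: LAC repressor substitutions
tolerant: 0.67
entropy_increasing: 0.31
entropy_decreasing: 0.02
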