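# Relative growth rates under the non-selecting condition
# (protein-burden fitness spectrum, relative to phenotype 7).
mu:
  1: 0.999997573
  3: 1.000000322
  5: 0.999997527
  6: 0.999997357
  7: 1.0
  8: 0.999999693
  11: 1.000000412
  15: 1.000000115
  16: 0.99999976
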