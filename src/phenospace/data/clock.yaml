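dependent_variables:
- mP
- P
- mN
- N
auxiliary_variables:
- DP
- DN
parameters:
  K_N: 0.316
  K_P: 1.78
  alpha_N: 1.0
  alpha_P: 0.01
  alpha_mNmax: 10.0
  alpha_mNmin: 1.0
  alpha_mPmax: 10000.0
  alpha_mPmin: 1.0
  beta_N: 1.0
  beta_P: 1.0
  beta_mN: 1.0
  beta_mP: 1.0
kinetic_orders:
  n: 2.0
  p: 2.0
equations:
- target: mP
  kind: differential
  positive_terms:
  - coefficient: 1.0
    exponents:
      alpha_mPmax: 1.0
      DP: -1.0
  - coefficient: 1.0
    exponents:
      alpha_mPmin: 1.0
      N: 2.0
      K_N: -2.0
      DP: -1.0
  negative_terms:
  - coefficient: 1.0
    exponents:
      beta_mP: 1.0
      mP: 1.0
- target: P
  kind: differential
  positive_terms:
  - coefficient: 1.0
    exponents:
      alpha_P: 1.0
      mP: 1.0
  negative_terms:
  - coefficient: 1.0
    exponents:
      beta_P: 1.0
      P: 1.0
- target: mN
  kind: differential
  positive_terms:
  - coefficient: 1.0
    exponents:
      alpha_mNmin: 1.0
      DN: -1.0
  - coefficient: 1.0
    exponents:
      alpha_mNmax: 1.0
      P: 2.0
      K_P: -2.0
      DN: -1.0
  negative_terms:
  - coefficient: 1.0
    exponents:
      beta_mN: 1.0
      mN: 1.0
- target: N
  kind: differential
  positive_terms:
  - coefficient: 1.0
    exponents:
      alpha_N: 1.0
      mN: 1.0
  negative_terms:
  - coefficient: 1.0
    exponents:
      beta_N: 1.0
      N: 1.0
- target: DP
  kind: algebraic
  positive_terms:
  - coefficient: 1.0
    exponents: {}
  - coefficient: 1.0
    exponents:
      N: 2.0
      K_N: -2.0
  negative_terms:
  - coefficient: 1.0
    exponents:
      DP: 1.0
- target: DN
  kind: algebraic
  positive_terms:
  - coefficient: 1.0
    exponents: {}
  - coefficient: 1.0
    exponents:
      P: 2.0
      K_P: -2.0
  negative_terms:
  - coefficient: 1.0
    exponents:
      DN: 1.0
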