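# SYNTHETIC population model parameter file.
# Two-compartment iohexol model with random effects on all parameters.
# Synthetic stand-in values; not fitted to any clinical dataset.
name: cmt2_full_synthetic
model:
  compartments: 2
  re_mask: [CL, V1, Q2, V2]
  covariates_enabled: false
theta:
  CL: 0.056
  V1: 9.5
  Q2: 0.105
  V2: 5.8
omega:
  - [0.17, 0.0, 0.0, 0.0]
  - [0.0, 0.06, 0.0, 0.0]
  - [0.0, 0.0, 0.12, 0.0]
  - [0.0, 0.0, 0.0, 0.12]
sigma:
  kind: proportional
  prop: 0.05
  add: 0.0
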