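# SYNTHETIC population model parameter file.
# Three-compartment iohexol model with random effects limited to CL and V1
# (all distributional parameters fixed at typical values).  Synthetic
# stand-in values; not fitted to any clinical dataset.
name: cmt3_limited_synthetic
model:
  compartments: 3
  re_mask: [CL, V1]
  covariates_enabled: false
theta:
  CL: 0.055
  V1: 7.9
  Q2: 0.18
  V2: 4.6
  Q3: 0.045
  V3: 3.6
omega:
  - [0.17, 0.0]
  - [0.0, 0.06]
sigma:
  kind: proportional
  prop: 0.05
  add: 0.0
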