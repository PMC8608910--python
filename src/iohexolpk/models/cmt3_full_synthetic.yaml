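# SYNTHETIC population model parameter file.
# Three-compartment iohexol model with random effects on all parameters.
# These values are synthetic stand-ins constructed from typical iohexol
# pharmacokinetics in elderly adults (CL ~ 55 mL/min, Vss ~ 16 L, i.e. the
# extracellular space); they are NOT estimates fitted to any clinical dataset.
name: cmt3_full_synthetic
model:
  compartments: 3
  re_mask: [CL, V1, Q2, V2, Q3, V3]
  covariates_enabled: false
theta:
  CL: 0.055     # L/min (55 mL/min)
  V1: 7.9       # L
  Q2: 0.18      # L/min
  V2: 4.6       # L
  Q3: 0.045     # L/min
  V3: 3.6       # L
omega:          # diagonal log-scale variances
  - [0.17, 0.0, 0.0, 0.0, 0.0, 0.0]
  - [0.0, 0.06, 0.0, 0.0, 0.0, 0.0]
  - [0.0, 0.0, 0.12, 0.0, 0.0, 0.0]
  - [0.0, 0.0, 0.0, 0.12, 0.0, 0.0]
  - [0.0, 0.0, 0.0, 0.0, 0.15, 0.0]
  - [0.0, 0.0, 0.0, 0.0, 0.0, 0.15]
sigma:
  kind: proportional
  prop: 0.05    # 5% CV
  add: 0.0
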