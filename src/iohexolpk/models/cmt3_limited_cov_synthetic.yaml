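# SYNTHETIC population model parameter file.
# Three-compartment iohexol model, random effects limited to CL and V1,
# with the power-law covariate model on CL (creatinine, cystatin C, age,
# weight, sex) and on V1 (weight).  Covariate exponents are synthetic
# stand-ins chosen so that covariate-predicted clearance tracks
# creatinine/cystatin-C-based eGFR; not fitted to any clinical dataset.
name: cmt3_limited_cov_synthetic
model:
  compartments: 3
  re_mask: [CL, V1]
  covariates_enabled: true
theta:
  CL: 0.0546        # typical clearance at reference covariates (L/min)
  V1: 7.9           # typical central volume at 77 kg (L)
  Q2: 0.18
  V2: 4.6
  Q3: 0.045
  V3: 3.6
  cr_exp: -0.38     # creatinine exponent (CR/0.9)
  cc_exp: -0.60     # cystatin C exponent (CC/1.03)
  age_exp: -0.30    # age exponent (age/77)
  weight_exp_cl: 0.42
  female_shift: -0.07
  weight_exp_v1: 0.80
omega:              # covariates explain much of the CL variability
  - [0.045, 0.0]
  - [0.0, 0.05]
sigma:
  kind: proportional
  prop: 0.05
  add: 0.0
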