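# Coefficients of the BIS2 estimated-GFR equation (creatinine + cystatin C),
# from the Berlin Initiative Study equation papers (Schaeffner et al.,
# Ann Intern Med 2012).  Kept in config rather than code so that alternative
# eGFR equations of the same power-law form can be swapped in.
#
# eGFR [mL/min/1.73 m^2] =
#   scale * CysC^cystatin_exp * Crea^creatinine_exp * age^age_exp
#   * female_factor (if female)
coefficients:
  scale: 767.0
  cystatin_exp: -0.61
  creatinine_exp: -0.40
  age_exp: -0.57
  female_factor: 0.87
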