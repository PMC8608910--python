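"""Empirical-Bayes (MAP) clearance estimation for a single subject.

Simulates one virtual patient from the limited three-compartment model
(random effects on CL and V1 only), then re-estimates the clearance from
the noisy concentrations using the population model as a prior — once with
all samples and once from just two samples (30 and 300 min).  The
two-sample estimate stays close to the truth because the prior supplies the
distributional parameters.
"""

import numpy as np

from iohexolpk import CohortSpec, EstimationSettings, estimate_ebe, load_bundled_model
from iohexolpk.simulate import simulate_subjects

pop = load_bundled_model("cmt3_limited")
spec = CohortSpec(n_subjects=1, seed=4)
subject = simulate_subjects(pop, spec)[0]

settings = EstimationSettings(phi=1.0, seed=0)
full = estimate_ebe(pop, subject.record, settings)
two = estimate_ebe(pop, subject.record.restricted(np.array([30.0, 300.0])), settings)

print(f"true clearance        : {subject.true_cl_ml_min:6.2f} mL/min")
print(f"EBE, all 9 samples    : {full.cl_ml_min:6.2f} mL/min")
print(f"EBE, 30 + 300 min only: {two.cl_ml_min:6.2f} mL/min")
print("\nThe all-samples estimate is nearly exact; the two-sample estimate is")
print("less precise but remains usable because the population prior (phi = 1)")
print("supplies the disposition phases the two draws cannot see.")
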