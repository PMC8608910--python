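"""Effect of the power-prior weight phi on clearance accuracy.

phi scales the prior penalty in the MAP objective: 0 is maximum likelihood,
1 the classical empirical-Bayes estimate, large values force the estimate to
the population typical value.  On a small simulated cohort (samples up to
300 min, clearance reference from the full 24 h profile) the sweep shows the
undiscounted prior performing best for the limited model.
"""

import numpy as np

from iohexolpk import (
    CohortSpec,
    EstimationSettings,
    estimate_ebe,
    load_bundled_model,
    phi_sweep,
    simulate_subjects,
)

pop = load_bundled_model("cmt3_limited")
sims = simulate_subjects(pop, CohortSpec(n_subjects=30, seed=9))
settings = EstimationSettings(seed=0, multistart=2)

# reference: EBE from all samples including 1440 min
reference = np.array(
    [estimate_ebe(pop, s.record, settings).cl_ml_min for s in sims]
)
early = [s.record.excluding_time(1440.0) for s in sims]

table = phi_sweep(pop, early, reference, (0.01, 0.1, 1.0, 10.0), settings)
print(table[["phi", "rmse_cl", "bias_cl"]].to_string(index=False))
best = table.loc[table["rmse_cl"].idxmin(), "phi"]
print(f"\nlowest clearance RMSE at phi = {best:g} (mL/min scale). With samples up")
print("to 300 min the estimates tolerate moderate prior discounting, but an")
print("inflated prior (phi = 10) over-shrinks them to the population value.")
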