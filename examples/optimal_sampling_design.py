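"""Find optimal limited-sampling times by exhaustive simulation-based search.

Simulates a cohort from the limited three-compartment model at the 7
candidate draw times, evaluates every 1- and 2-sample design by
re-estimating each subject's clearance from only the design's samples, and
ranks designs by RMSE against the simulated true clearance.
"""

from iohexolpk import (
    CohortSpec,
    EstimationSettings,
    enumerate_designs,
    evaluate_all_designs,
    load_bundled_model,
    optimize_designs,
    simulate_subjects,
)
from iohexolpk.design import SIMULATION_CANDIDATE_TIMES
from iohexolpk.simulate import true_clearances

pop = load_bundled_model("cmt3_limited")
spec = CohortSpec.simulation_grid(n_subjects=150, seed=3)
sims = simulate_subjects(pop, spec)
subjects = [s.record for s in sims]
reference = true_clearances(sims)

designs = enumerate_designs(SIMULATION_CANDIDATE_TIMES, 1, 2)
evals = evaluate_all_designs(
    designs, subjects, pop, reference,
    settings=EstimationSettings(seed=0, multistart=2),
)
optima = optimize_designs(evals, criteria=("rmse_cl",))["rmse_cl"]

print("best design per number of samples (clearance RMSE vs simulated truth):")
for size, ev in optima.items():
    times = ", ".join(f"{t:g}" for t in ev.design.times)
    print(f"  N={size}: draw at {times} min   RMSE = {ev.rmse_cl:.2f} mL/min")
print("\nA late draw anchors the elimination phase; adding one earlier draw")
print("pins the distribution phase and further reduces the clearance error.")
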