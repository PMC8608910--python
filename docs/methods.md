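# Methods

## Scope and model

`iohexolpk` estimates iohexol plasma clearance — a reference measure of the
glomerular filtration rate (GFR) — from sparse concentration data after an
intravenous bolus, using a population pharmacokinetic model as a Bayesian
prior, and searches for the blood-sampling schedules that preserve the
accuracy of that estimate.

Disposition is described by linear mammillary two- or three-compartment
models with elimination clearance CL from the central volume V1 and
inter-compartmental clearances Q2 (and Q3) into peripheral volumes V2 (and
V3). The bolus response is obtained in closed form from the
eigendecomposition of the micro-rate-constant matrix; working units are L,
min and mg, so predicted mg/L equals the assay's µg/mL. For any linear model
AUC(0,∞) = dose/CL, which the tests verify by independent quadrature.

Between-subject variability is log-normal: the p-th individual parameter is
`PK_i = PK_typ · exp(eta_i)`, with `eta ~ MVN(0, Omega)` over the masked
parameters. Two random-effect structures are supported: *full* (all
structural parameters) and *limited* (CL and V1 only, all distributional
parameters fixed at typical values). Covariates enter multiplicatively on CL
(serum creatinine, cystatin C, age, body weight as power functions of the
covariate normalised to its cohort median — 0.9 mg/dL, 1.03 mg/L, 77 y,
77 kg — plus a proportional female shift) and on V1 (weight). Auxiliary
clinical formulas: Du Bois body-surface area and a configurable
power-law creatinine + cystatin C eGFR equation whose published (BIS2)
coefficients ship as a config file, not as code constants.

## Individual estimation (MAP with a power prior)

For subject *i* with observations `y_ij` the penalised -2 log-likelihood is

    OBJ_i(eta) = sum_j [ log sigma_ij^2 + (y_ij - IPRED_ij)^2 / sigma_ij^2 ]
                 + phi * eta' Omega^-1 eta

with residual variance `sigma_ij^2` from a proportional, additive or
combined error model. `phi` is the power-prior weight: 0 gives maximum
likelihood (only defined when the subject has at least as many observations
as random effects), 1 the classical empirical-Bayes (MAP) estimate, and
large values collapse the estimate to the population typical value. The
minimiser is found by L-BFGS-B (numerical gradients, objective tolerance
1e-10) from the prior mode plus seeded jittered multistarts (default 5,
jitter SD 0.3) because three-compartment fits on sparse data can be
multi-modal; eta is box-bounded at ±10 purely to keep the line search from
overflowing `exp(eta)`. Estimation is deterministic for a fixed seed (the
jitter stream derives from the seed and the subject id).

A subtlety worth knowing: with a *proportional* error model the
log-variance term depends on the prediction, so even noiseless data do not
place the optimum exactly at the simulated eta — the optimum trades a
slightly smaller prediction against zero residuals. This is a property of
the objective, not an optimiser defect; exact-recovery tests therefore use
an additive (homoscedastic) error model, for which the statement is exact.

## Population fitting

Fixed effects are (re-)estimated by maximising the Laplace approximation to
the marginal likelihood: for each subject the inner MAP problem is solved
(phi = 1, warm-started across outer iterations), the inner Hessian is
obtained by central differences, and the subject's contribution is
`OBJ_i(eta_hat) + n_i log 2*pi + log det Omega + log det(H_i/2)`. The outer
optimiser is L-BFGS-B over log-transformed structural parameters (covariate
exponents untransformed; the female shift via log1p). Omega and sigma stay
fixed at their configured values — the conventional workflow when
transporting a published model to new data — and any parameter can be held
fixed by name. Reported OFV is -2 log L, so nested-model differences are
chi-squared comparable. This is a Laplace, not FOCE-I, implementation: a
deliberate, documented approximation difference from classical NONMEM fits.

## Agreement metrics

Estimates are compared to reference clearances with: RMSE and bias
(estimate minus reference); Lin's concordance correlation coefficient using
population (1/n) moments, with the conventional bands ≥ 0.99 almost
perfect, [0.95, 0.99) substantial, [0.90, 0.95) moderate, < 0.90 poor
(bands taken left-closed since the printed limits overlap); the relative
total deviation index TDI(CP), computed as the empirical CP-quantile of
|est − ref|/|ref| with linear interpolation between order statistics (the
source literature does not fix a quantile convention; this one is
documented and frozen); and P10/P30, the percentage of subjects within
10%/30% of the reference. The TDI target used in design evaluation is
TDI ≤ 10% at CP = 0.90.

## Design search

Sampling designs are subsets of a candidate grid; the search is exhaustive
over sizes 1–4 (at most a few hundred subsets). Two grids are bundled: the
7-point simulation grid (30, 60, 90, 120, 180, 240, 300 min) and the
8-point observed-protocol grid that adds 150 min; a variant extending the
simulation grid with 360 and 480 min is available via config. Each design
is scored by re-running the MAP estimation per subject using only the
design's samples, against either the simulated true clearance (simulation
mode) or the all-samples estimate (observed mode). Clearance RMSE and the
RMSE of predicted 1440-min concentrations are ranked *separately* — they
can favour different times and no principled scalar combination exists —
with ties broken by the earliest final sample time, then lexicographically.
Optional stratification groups subjects by eGFR, either at fixed cutoffs
(< 23 / 23–34 / > 34 mL/min) or at data-driven quartiles.

## Synthetic cohorts

The generator emulates an elderly (70+) population undergoing iohexol
clearance measurement: covariates drawn independently from normal (or
optionally log-normal) marginals truncated at physiologic floors
(age ≥ 70 per the inclusion criterion, weight > 30 kg, positive
creatinine/cystatin C), a 33% female fraction, an IV bolus of 3235 mg, the
30–300 min protocol grid with an optional 1440-min draw, log-normal
between-subject variability and residual noise per the model's error model.
Defaults describe a reduced-GFR cohort (age 79.2 ± 6.1 y, weight
79.5 ± 13.9 kg, creatinine 1.91 ± 0.60 mg/dL, cystatin C 2.13 ± 0.75 mg/L);
a second preset describes the larger moderate-GFR development-type cohort,
and a third the stochastic design-simulation setting (7-point grid, 6,500
subjects — ten times the combined 546 + 104 study size). Simulation truth
(eta, clearance, noiseless profiles) is retained in memory and written only
to a sidecar file, never into the analysis dataset.

What the generator does *not* emulate: covariate correlations are off by
default (no joint distribution is published; a Gaussian-copula
creatinine–cystatin C correlation can be enabled), covariates do not feed
back into the non-covariate models' parameters, there is no
below-quantification-limit censoring, no inter-occasion variability and no
assay drift. Passing tests therefore demonstrate internal consistency of
the estimation/design machinery under the assumed data-generating process,
not performance on any real cohort.

## Parameter values and their provenance

The bundled model files are **synthetic stand-ins**, not estimates fitted
to clinical data: typical values (CL 55 mL/min, V1 7.9 L, Vss ≈ 16 L —
the extracellular space), variances (ω²_CL 0.17 full/limited, 0.045 with
covariates; ω²_V1 0.05–0.06) and a 5% proportional residual CV were chosen
once as representative of iohexol kinetics in elderly adults and of HPLC
assay precision. Covariate exponents were chosen so that covariate-predicted
clearance tracks creatinine/cystatin-C-based eGFR. Conclusions that depend
on the exact parameter values (e.g. which single sampling time is optimal)
are therefore illustrative; the machinery, not the numbers, is the product.

## Numerical choices and problem sizes

Near-coincident eigenvalues (relative gap < 1e-9 with an ill-conditioned
eigenvector matrix) are resolved by a symmetric 1e-8 relative perturbation
of the peripheral volumes. Degenerate inputs fail loudly: non-positive
parameters or covariates, singular or non-PD Omega with phi > 0, missing
observations at design times (no imputation), datasets without exactly one
dose record per subject. Dataset round trips are lossless to 12 significant
digits. Default problem sizes in the tests and the acceptance script are
scaled to a single CPU — 104-subject evaluation cohorts, 1,000-subject
design simulations (600 for two-sample designs), 200-subject parameter
recovery — sizes at which the Monte-Carlo error is small relative to every
asserted margin; the study-scale 6,500-subject default remains available.

## Known limitations

Laplace (not FOCE-I/SAEM) population fitting; no inter-occasion
variability; no BLQ handling; IV bolus only; Omega/sigma estimation limited
to fixed values by default; the design search is exhaustive over a discrete
grid rather than continuous-time (Ds-)optimal design.
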