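"""Virtual cohort generation for iohexol clearance studies.

Emulates the statistical structure the analysis assumes for elderly
patients undergoing iohexol plasma-clearance measurement: covariate
marginals matching published cohort summaries (age 70+, roughly one third
to one half women, creatinine/cystatin C elevated in the reduced-GFR
group), an IV bolus of 3235 mg iohexol, draws on a fixed protocol grid up
to 300 min with an optional 1440-min (24 h) sample, log-normal
between-subject variability eta ~ MVN(0, Omega) on the masked parameters,
and residual error on observed concentrations.

Covariates are sampled independently per marginal by default (no joint
distribution is published for these cohorts); an optional Gaussian-copula
correlation between creatinine and cystatin C is available because the two
markers are strongly correlated in practice.  The simulated truth (eta,
clearance, noiseless profiles) is retained on each subject but is written
only to the sidecar file, never into the analysis dataset.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .dataio import SubjectRecord
from .pk_models import Covariates, InvalidParameterError
from .population import PopulationModel, individual_params

__all__ = [
    "CohortSpec",
    "SimulatedSubject",
    "sample_covariates",
    "simulate_subjects",
    "true_clearances",
]

PROTOCOL_TIMES = (30.0, 60.0, 90.0, 120.0, 150.0, 180.0, 240.0, 300.0)


@dataclass(frozen=True)
class CohortSpec:
    """Study-condition description of a virtual cohort.

    Defaults reproduce the evaluation-type cohort: 104 elderly patients
    with substantially reduced kidney function, 33% female, dosed with
    3235 mg iohexol and sampled on the 30-300 min protocol grid plus a
    24-hour draw.
    """

    n_subjects: int = 104
    female_fraction: float = 0.33
    age_mean: float = 79.2
    age_sd: float = 6.09
    weight_mean: float = 79.5
    weight_sd: float = 13.9
    height_mean: float = 1.68
    height_sd: float = 0.094
    creatinine_mean: float = 1.91
    creatinine_sd: float = 0.603
    cystatin_mean: float = 2.13
    cystatin_sd: float = 0.745
    lognormal_covariates: tuple[str, ...] = ()
    cr_cc_correlation: float = 0.0
    dose_mg: float = 3235.0
    times: tuple[float, ...] = PROTOCOL_TIMES
    include_1440: bool = True
    residual_noise: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_subjects < 1:
            raise InvalidParameterError("n_subjects must be at least 1")
        for name in ("age_sd", "weight_sd", "height_sd", "creatinine_sd", "cystatin_sd"):
            if getattr(self, name) < 0:
                raise InvalidParameterError(f"{name} must be non-negative")
        if not 0.0 <= self.female_fraction <= 1.0:
            raise InvalidParameterError("female_fraction must lie in [0, 1]")
        if not -1.0 < self.cr_cc_correlation < 1.0:
            raise InvalidParameterError("cr_cc_correlation must lie in (-1, 1)")
        object.__setattr__(self, "times", tuple(sorted(float(t) for t in self.times)))

    @property
    def all_times(self) -> tuple[float, ...]:
        return self.times + ((1440.0,) if self.include_1440 else ())

    @classmethod
    def development_like(cls, **overrides) -> "CohortSpec":
        """Cohort resembling the model-development group (n=546, moderate GFR)."""
        base = dict(
            n_subjects=546,
            female_fraction=0.44,
            age_mean=78.3,
            age_sd=6.03,
            weight_mean=77.3,
            weight_sd=13.9,
            creatinine_mean=0.962,
            creatinine_sd=0.289,
            cystatin_mean=1.11,
            cystatin_sd=0.309,
            include_1440=False,
        )
        base.update(overrides)
        return cls(**base)

    @classmethod
    def simulation_grid(cls, **overrides) -> "CohortSpec":
        """Cohort sampled on the 7-point simulation grid (no 150 min, no 24 h).

        Defaults to 6,500 subjects — ten times the combined development and
        evaluation study size (546 + 104) — the convention for
        simulation-based design evaluation.
        """
        base = dict(
            n_subjects=10 * (546 + 104),
            times=(30.0, 60.0, 90.0, 120.0, 180.0, 240.0, 300.0),
            include_1440=False,
        )
        base.update(overrides)
        return cls(**base)


# physiologic floors applied by rejection sampling
_FLOORS = {
    "age": 70.0,
    "weight": 30.0,
    "height": 1.2,
    "creatinine": 0.05,
    "cystatin_c": 0.05,
}


def _truncated_draw(
    rng: np.random.Generator, mean: float, sd: float, floor: float, n: int, lognormal: bool
) -> np.ndarray:
    """Draw n values from the marginal, resampling any below the floor."""
    if sd == 0:
        if mean < floor:
            raise InvalidParameterError(f"degenerate marginal at {mean} violates floor {floor}")
        return np.full(n, float(mean))
    out = np.empty(n)
    todo = np.arange(n)
    for _ in range(1000):
        out[todo] = _marginal(rng, mean, sd, todo.size, lognormal)
        todo = np.flatnonzero(out < floor)
        if todo.size == 0:
            return out
    raise InvalidParameterError(
        f"could not satisfy floor {floor} for marginal mean={mean}, sd={sd}"
    )


def _marginal(rng, mean, sd, n, lognormal) -> np.ndarray:
    if lognormal:
        # match mean/sd on the natural scale
        var_log = np.log1p((sd / mean) ** 2)
        mu = np.log(mean) - var_log / 2
        return rng.lognormal(mu, np.sqrt(var_log), size=n)
    return rng.normal(mean, sd, size=n)


def sample_covariates(spec: CohortSpec, rng: np.random.Generator | None = None) -> pd.DataFrame:
    """Draw a covariate table (one row per subject) per the cohort spec.

    Marginals are normal (or log-normal per ``lognormal_covariates``),
    truncated at physiologic floors by resampling (age >= 70 per the 70+
    inclusion criterion, weight > 30 kg, positive creatinine/cystatin C).
    Creatinine and cystatin C can share a Gaussian-copula correlation.
    """
    rng = rng if rng is not None else np.random.default_rng(spec.seed)
    n = spec.n_subjects
    ln = set(spec.lognormal_covariates)
    cols = {"id": np.arange(1, n + 1)}
    cols["female"] = rng.random(n) < spec.female_fraction
    cols["age"] = _truncated_draw(rng, spec.age_mean, spec.age_sd, _FLOORS["age"], n, "age" in ln)
    cols["weight"] = _truncated_draw(
        rng, spec.weight_mean, spec.weight_sd, _FLOORS["weight"], n, "weight" in ln
    )
    cols["height"] = _truncated_draw(
        rng, spec.height_mean, spec.height_sd, _FLOORS["height"], n, "height" in ln
    )
    if spec.cr_cc_correlation != 0.0:
        rho = spec.cr_cc_correlation
        z = rng.multivariate_normal(
            [0.0, 0.0], [[1.0, rho], [rho, 1.0]], size=n, method="cholesky"
        )
        from scipy.stats import norm

        u = norm.cdf(z)
        cr = spec.creatinine_mean + spec.creatinine_sd * norm.ppf(u[:, 0])
        cc = spec.cystatin_mean + spec.cystatin_sd * norm.ppf(u[:, 1])
        cols["creatinine"] = np.maximum(cr, _FLOORS["creatinine"])
        cols["cystatin_c"] = np.maximum(cc, _FLOORS["cystatin_c"])
    else:
        cols["creatinine"] = _truncated_draw(
            rng, spec.creatinine_mean, spec.creatinine_sd, _FLOORS["creatinine"], n,
            "creatinine" in ln,
        )
        cols["cystatin_c"] = _truncated_draw(
            rng, spec.cystatin_mean, spec.cystatin_sd, _FLOORS["cystatin_c"], n,
            "cystatin_c" in ln,
        )
    return pd.DataFrame(cols)


@dataclass(frozen=True)
class SimulatedSubject:
    """A virtual subject: observable record plus retained simulation truth."""

    record: SubjectRecord
    true_eta: np.ndarray
    true_params: object  # StructuralParams
    re_mask: tuple[str, ...]
    noiseless: np.ndarray

    @property
    def true_cl_ml_min(self) -> float:
        return self.true_params.cl_ml_min

    @property
    def subject_id(self) -> int:
        return self.record.subject_id


def simulate_subjects(
    pop: PopulationModel,
    spec: CohortSpec,
    rng: np.random.Generator | None = None,
) -> list[SimulatedSubject]:
    """Simulate a cohort from a population model under the cohort spec.

    Per subject: covariates (used by the model if it has a covariate
    submodel), eta ~ MVN(0, Omega) via a Cholesky draw, individual
    parameters ``typical * exp(eta)``, a noiseless profile at the protocol
    times, and — unless ``spec.residual_noise`` is off — observed values
    perturbed per the model's residual error model.  Bit-reproducible for a
    fixed seed (single sequential stream, fixed draw order).
    """
    from .pk_models import predict_concentration  # local import to keep module load light

    rng = rng if rng is not None else np.random.default_rng(spec.seed)
    cov_table = sample_covariates(spec, rng)
    chol = pop.omega_cholesky()
    k = pop.n_random_effects
    times = np.asarray(spec.all_times)
    out: list[SimulatedSubject] = []
    for row in cov_table.itertuples(index=False):
        cov = Covariates(
            age=row.age,
            sex="female" if row.female else "male",
            weight=row.weight,
            creatinine=row.creatinine,
            cystatin_c=row.cystatin_c,
            height=row.height,
        )
        eta = chol @ rng.standard_normal(k)
        params = individual_params(pop, eta, cov)
        noiseless = predict_concentration(params, spec.dose_mg, times)
        dv = noiseless.copy()
        if spec.residual_noise:
            eps = rng.standard_normal(times.size)
            sd = np.sqrt(pop.residual.variance(noiseless))
            dv = noiseless + sd * eps
        record = SubjectRecord(
            subject_id=int(row.id),
            dose_mg=spec.dose_mg,
            times=times,
            concentrations=dv,
            covariates=cov,
        )
        out.append(
            SimulatedSubject(
                record=record,
                true_eta=eta,
                true_params=params,
                re_mask=pop.re_mask,
                noiseless=noiseless,
            )
        )
    return out


def true_clearances(subjects: list[SimulatedSubject]) -> np.ndarray:
    """True simulated clearances (mL/min), aligned with the subject list."""
    return np.array([s.true_cl_ml_min for s in subjects])
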