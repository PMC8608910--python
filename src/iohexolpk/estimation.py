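"""Individual MAP (empirical-Bayes) estimation and population fitting.

The individual-level objective for subject *i* is the penalised -2
log-likelihood

    OBJ_i(eta) = sum_j [ log sigma_ij^2 + (y_ij - IPRED_ij)^2 / sigma_ij^2 ]
                 + phi * eta' Omega^-1 eta

where IPRED are the model predictions at the subject's individual
parameters and the power-prior weight ``phi`` scales the influence of the
population distribution: ``phi = 0`` is plain maximum likelihood, ``phi = 1``
the classical empirical-Bayes (MAP) estimate, and large ``phi`` forces the
estimate to the population typical values (shrinkage).

Population fixed effects are (re-)estimated by maximising the Laplace
approximation to the marginal likelihood, with Omega and sigma fixed at
their configured values by default.
"""

from __future__ import annotations

from dataclasses import dataclass, replace as dc_replace
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import optimize

from .dataio import SubjectRecord
from .pk_models import (
    InvalidParameterError,
    StructuralParams,
    predict_concentration,
)
from .population import PopulationModel, ResidualModel, individual_params

__all__ = [
    "EstimationError",
    "UnidentifiableError",
    "EstimationSettings",
    "EBEResult",
    "map_objective",
    "estimate_ebe",
    "phi_sweep",
    "fit_population",
    "PopulationFitResult",
    "ResidualModel",
]


class EstimationError(RuntimeError):
    pass


class UnidentifiableError(EstimationError):
    """Maximum likelihood requested with fewer observations than random effects."""


@dataclass(frozen=True)
class EstimationSettings:
    """Controls for the inner (per-subject) MAP optimisation.

    phi is the power-prior weight; ``multistart`` jittered restarts guard
    against local minima of sparse-data three-compartment fits; the jitter
    stream is derived deterministically from ``seed`` and the subject id.
    """

    phi: float = 1.0
    tol: float = 1e-10
    multistart: int = 5
    jitter_sd: float = 0.3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.phi < 0:
            raise InvalidParameterError(f"phi must be non-negative, got {self.phi}")
        if self.multistart < 1:
            raise InvalidParameterError("multistart must be at least 1")


@dataclass(frozen=True)
class EBEResult:
    """Outcome of one subject's MAP estimation."""

    subject_id: int
    eta_hat: np.ndarray
    params: StructuralParams
    objective: float
    converged: bool
    phi_used: float
    n_obs: int

    @property
    def cl_ml_min(self) -> float:
        return self.params.cl_ml_min

    def predict(self, times) -> np.ndarray:
        """Concentrations (µg/mL) at the individual parameter estimates."""
        return predict_concentration(self.params, self._dose, times)

    # dose is carried privately so that predict() needs no extra arguments
    _dose: float = 3235.0


class _SubjectContext:
    """Precomputed quantities reused across objective evaluations."""

    __slots__ = ("pop", "subj", "base", "omega_inv", "y")

    def __init__(self, pop: PopulationModel, subj: SubjectRecord, phi: float):
        self.pop = pop
        self.subj = subj
        self.base = pop.typical_params(subj.covariates)
        self.y = subj.concentrations
        if phi > 0:
            self.omega_inv = pop.omega_inverse()
        else:
            self.omega_inv = None

    def objective(self, eta: np.ndarray, phi: float) -> float:
        mask = self.pop.re_mask
        updates = {p: getattr(self.base, p) * np.exp(e) for p, e in zip(mask, eta)}
        params = self.base.replace(**updates)
        total = 0.0
        if self.subj.n_obs:
            ipred = predict_concentration(params, self.subj.dose_mg, self.subj.times)
            var = self.pop.residual.variance(ipred)
            if np.any(var <= 0):
                raise EstimationError(
                    "non-positive residual variance encountered (proportional error "
                    "with vanishing prediction?)"
                )
            res = self.y - ipred
            total = float(np.sum(np.log(var) + res**2 / var))
        if phi > 0:
            eta = np.asarray(eta, dtype=float)
            total += phi * float(eta @ self.omega_inv @ eta)
        return total


def map_objective(
    pop: PopulationModel, subj: SubjectRecord, eta: np.ndarray, phi: float
) -> float:
    """Power-prior MAP objective OBJ_i for one subject (see module docstring)."""
    if phi < 0:
        raise InvalidParameterError(f"phi must be non-negative, got {phi}")
    eta = np.asarray(eta, dtype=float)
    if eta.shape != (pop.n_random_effects,):
        raise InvalidParameterError(
            f"eta has shape {eta.shape}, expected ({pop.n_random_effects},)"
        )
    return _SubjectContext(pop, subj, phi).objective(eta, phi)


def _jitter_starts(
    k: int, settings: EstimationSettings, subject_id: int
) -> list[np.ndarray]:
    starts = [np.zeros(k)]
    if settings.multistart > 1:
        rng = np.random.default_rng(
            np.random.SeedSequence([settings.seed, int(subject_id) & 0x7FFFFFFF])
        )
        for _ in range(settings.multistart - 1):
            starts.append(rng.normal(0.0, settings.jitter_sd, size=k))
    return starts


def estimate_ebe(
    pop: PopulationModel,
    subj: SubjectRecord,
    settings: EstimationSettings | None = None,
    *,
    warm_start: np.ndarray | None = None,
) -> EBEResult:
    """MAP estimate of a subject's random effects and individual parameters.

    Deterministic for a fixed ``settings.seed``.  Raises
    :class:`UnidentifiableError` when ``phi == 0`` and the subject has fewer
    observations than random effects (plain ML is then ill-posed).
    """
    settings = settings or EstimationSettings()
    k = pop.n_random_effects
    phi = settings.phi
    if phi == 0 and subj.n_obs < k:
        raise UnidentifiableError(
            f"subject {subj.subject_id}: {subj.n_obs} observations cannot identify "
            f"{k} random effects without a prior (phi=0)"
        )
    if subj.n_obs == 0:
        # prior mode: with no data the penalty is minimised at eta = 0
        params = individual_params(pop, np.zeros(k), subj.covariates)
        return EBEResult(
            subject_id=subj.subject_id,
            eta_hat=np.zeros(k),
            params=params,
            objective=0.0,
            converged=True,
            phi_used=phi,
            n_obs=0,
            _dose=subj.dose_mg,
        )
    ctx = _SubjectContext(pop, subj, phi)

    def fun(eta: np.ndarray) -> float:
        try:
            value = ctx.objective(eta, phi)
        except (InvalidParameterError, EstimationError):
            # overflowing parameters or underflowing predictions at an
            # extreme trial point: repel the line search, don't abort
            return 1e12
        return value if np.isfinite(value) else 1e12

    starts = _jitter_starts(k, settings, subj.subject_id)
    if warm_start is not None:
        starts.insert(0, np.asarray(warm_start, dtype=float))
    # |eta| <= 10 spans a >20,000-fold parameter range; it only guards the
    # line search against overflow, never binds at a genuine optimum
    bounds = [(-10.0, 10.0)] * k
    best = None
    any_converged = False
    for x0 in starts:
        res = optimize.minimize(
            fun,
            x0,
            method="L-BFGS-B",
            bounds=bounds,
            options={"ftol": settings.tol, "gtol": 1e-10, "maxiter": 500},
        )
        any_converged = any_converged or bool(res.success)
        if best is None or res.fun < best.fun:
            best = res
    eta_hat = np.asarray(best.x, dtype=float)
    params = individual_params(pop, eta_hat, subj.covariates)
    return EBEResult(
        subject_id=subj.subject_id,
        eta_hat=eta_hat,
        params=params,
        objective=float(best.fun),
        converged=any_converged,
        phi_used=phi,
        n_obs=subj.n_obs,
        _dose=subj.dose_mg,
    )


def phi_sweep(
    pop: PopulationModel,
    subjects: Sequence[SubjectRecord],
    reference_cl: np.ndarray,
    phis: Iterable[float],
    settings: EstimationSettings | None = None,
    *,
    reference_conc: np.ndarray | None = None,
    conc_time: float = 1440.0,
) -> pd.DataFrame:
    """RMSE of clearance (and optionally late concentrations) per prior weight.

    For each phi, every subject is re-estimated from scratch and clearance
    RMSE is computed against ``reference_cl`` (mL/min); if
    ``reference_conc`` is given, predicted concentrations at ``conc_time``
    are scored against it.  Subjects for which a phi value is unidentifiable
    are counted in ``n_failed`` and excluded from that row's metrics.
    """
    subjects = list(subjects)
    if not subjects:
        raise EstimationError("phi_sweep needs at least one subject")
    reference_cl = np.asarray(reference_cl, dtype=float)
    if reference_cl.shape != (len(subjects),):
        raise EstimationError("reference_cl length must match the subject list")
    settings = settings or EstimationSettings()
    rows = []
    for phi in phis:
        run = dc_replace(settings, phi=float(phi))
        cl_hat = np.full(len(subjects), np.nan)
        conc_hat = np.full(len(subjects), np.nan)
        n_failed = 0
        for i, subj in enumerate(subjects):
            try:
                ebe = estimate_ebe(pop, subj, run)
            except UnidentifiableError:
                n_failed += 1
                continue
            cl_hat[i] = ebe.cl_ml_min
            conc_hat[i] = predict_concentration(ebe.params, subj.dose_mg, conc_time)[0]
        ok = ~np.isnan(cl_hat)
        row = {"phi": float(phi), "n_failed": n_failed, "n_used": int(ok.sum())}
        if ok.any():
            d = cl_hat[ok] - reference_cl[ok]
            row["rmse_cl"] = float(np.sqrt(np.mean(d**2)))
            row["bias_cl"] = float(np.mean(d))
        else:
            row["rmse_cl"] = np.nan
            row["bias_cl"] = np.nan
        if reference_conc is not None:
            ref = np.asarray(reference_conc, dtype=float)
            dc = conc_hat[ok] - ref[ok]
            row["rmse_conc"] = float(np.sqrt(np.mean(dc**2))) if ok.any() else np.nan
            row["bias_conc"] = float(np.mean(dc)) if ok.any() else np.nan
        rows.append(row)
    return pd.DataFrame(rows)


# -- population fitting -----------------------------------------------------

_COVARIATE_PARAM_NAMES = (
    "cr_exp",
    "cc_exp",
    "age_exp",
    "weight_exp_cl",
    "female_shift",
    "weight_exp_v1",
)


@dataclass(frozen=True)
class PopulationFitResult:
    model: PopulationModel
    ofv: float
    converged: bool
    n_outer_evals: int


def _hessian(fun, x: np.ndarray, step: float = 1e-4) -> np.ndarray:
    """Central finite-difference Hessian."""
    k = x.size
    H = np.empty((k, k))
    f0 = fun(x)
    for i in range(k):
        ei = np.zeros(k)
        ei[i] = step
        fpp = fun(x + ei)
        fmm = fun(x - ei)
        H[i, i] = (fpp - 2 * f0 + fmm) / step**2
        for j in range(i + 1, k):
            ej = np.zeros(k)
            ej[j] = step
            fij = fun(x + ei + ej)
            fi_j = fun(x + ei - ej)
            f_ij = fun(x - ei + ej)
            f__ = fun(x - ei - ej)
            H[i, j] = H[j, i] = (fij - fi_j - f_ij + f__) / (4 * step**2)
    return H


def _laplace_ofv(
    pop: PopulationModel,
    subjects: Sequence[SubjectRecord],
    settings: EstimationSettings,
    warm: dict[int, np.ndarray],
) -> float:
    """-2 log marginal likelihood under the Laplace approximation."""
    sign, logdet_omega = np.linalg.slogdet(pop.omega)
    if sign <= 0:
        raise EstimationError("omega must be positive definite for Laplace fitting")
    total = 0.0
    for subj in subjects:
        ebe = estimate_ebe(pop, subj, settings, warm_start=warm.get(subj.subject_id))
        warm[subj.subject_id] = ebe.eta_hat
        ctx = _SubjectContext(pop, subj, settings.phi)
        H = _hessian(lambda e: ctx.objective(e, settings.phi), ebe.eta_hat)
        # guard: a slightly indefinite numerical Hessian is clipped
        eigvals = np.linalg.eigvalsh((H + H.T) / 2)
        eigvals = np.maximum(eigvals, 1e-10)
        logdet_half_h = float(np.sum(np.log(eigvals / 2)))
        total += (
            ebe.objective
            + subj.n_obs * np.log(2 * np.pi)
            + logdet_omega
            + logdet_half_h
        )
    return total


def _free_parameters(
    pop: PopulationModel, fix: frozenset[str]
) -> list[tuple[str, str]]:
    names = []
    struct_names = ("CL", "V1", "Q2", "V2") + (
        ("Q3", "V3") if pop.structural.n_compartments == 3 else ()
    )
    for n in struct_names:
        if n not in fix:
            names.append((n, "log"))
    if pop.covariates is not None:
        for n in _COVARIATE_PARAM_NAMES:
            if n not in fix:
                names.append((n, "log1p" if n == "female_shift" else "identity"))
    return names


def _pack(pop: PopulationModel, free: list[tuple[str, str]]) -> np.ndarray:
    x = []
    for name, tf in free:
        if hasattr(pop.structural, name):
            v = getattr(pop.structural, name)
        else:
            v = getattr(pop.covariates, name)
        x.append(np.log(v) if tf == "log" else np.log1p(v) if tf == "log1p" else v)
    return np.asarray(x, dtype=float)


def _unpack(
    pop: PopulationModel, free: list[tuple[str, str]], x: np.ndarray
) -> PopulationModel:
    struct_updates: dict[str, float] = {}
    cov_updates: dict[str, float] = {}
    for (name, tf), xi in zip(free, x):
        v = np.exp(xi) if tf == "log" else np.expm1(xi) if tf == "log1p" else xi
        if hasattr(pop.structural, name):
            struct_updates[name] = float(v)
        else:
            cov_updates[name] = float(v)
    structural = pop.structural.replace(**struct_updates)
    covariates = pop.covariates
    if cov_updates:
        covariates = dc_replace(covariates, **cov_updates)
    if covariates is not None:
        covariates = dc_replace(
            covariates, typical_cl=structural.CL, typical_v1=structural.V1
        )
    return dc_replace(pop, structural=structural, covariates=covariates)


def fit_population(
    subjects: Sequence[SubjectRecord],
    start: PopulationModel,
    *,
    fix: Iterable[str] = (),
    settings: EstimationSettings | None = None,
    maxiter: int = 200,
) -> PopulationFitResult:
    """Re-estimate population fixed effects by Laplace marginal likelihood.

    Omega and the residual model are held fixed at the values in ``start``
    (the conventional workflow when transporting a published model to new
    data); parameter names listed in ``fix`` are also held fixed.  Reported
    ``ofv`` is -2 log-likelihood, so nested-model OFV differences are
    chi-squared-comparable.
    """
    subjects = list(subjects)
    if len(subjects) < 2:
        raise EstimationError("population fitting needs at least two subjects")
    settings = settings or EstimationSettings(multistart=1)
    inner = dc_replace(settings, phi=1.0, multistart=1)
    free = _free_parameters(start, frozenset(fix))
    if not free:
        raise EstimationError("no free parameters to estimate")
    warm: dict[int, np.ndarray] = {}
    n_evals = 0

    def objective(x: np.ndarray) -> float:
        nonlocal n_evals
        n_evals += 1
        try:
            pop = _unpack(start, free, x)
        except InvalidParameterError:
            return 1e12
        return _laplace_ofv(pop, subjects, inner, warm)

    x0 = _pack(start, free)
    res = optimize.minimize(
        objective,
        x0,
        method="L-BFGS-B",
        options={"ftol": 1e-10, "gtol": 1e-7, "eps": 1e-4, "maxiter": maxiter},
    )
    fitted = _unpack(start, free, res.x)
    return PopulationFitResult(
        model=fitted,
        ofv=float(res.fun),
        converged=bool(res.success),
        n_outer_evals=n_evals,
    )
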