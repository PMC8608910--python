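"""Analytic compartmental models of iohexol disposition and clinical formulas.

Iohexol is eliminated almost exclusively by glomerular filtration, so its
plasma clearance after an intravenous bolus is a reference method for
measured GFR.  This module provides the structural pharmacokinetic layer:

* mammillary two- and three-compartment IV-bolus models solved analytically
  via eigen-decomposition of the micro-rate-constant matrix,
* a multiplicative (power-law) covariate model for elimination clearance and
  central volume,
* the Du Bois body-surface-area formula and a configurable
  creatinine + cystatin C eGFR equation.

Internal units are L, min and mg throughout, so that predicted amounts per
litre (mg/L) are numerically identical to the µg/mL scale of the assay.
Clearance is reported externally in mL/min.
"""

from __future__ import annotations

from collections.abc import Mapping
from dataclasses import dataclass
from typing import Literal

import numpy as np

__all__ = [
    "StructuralParams",
    "Covariates",
    "CovariateCoefficients",
    "InvalidParameterError",
    "predict_concentration",
    "apply_covariates",
    "bsa_dubois",
    "egfr_bis2",
]

#: Covariate normalisation constants of the clearance/volume covariate model
#: (cohort medians: creatinine 0.9 mg/dL, cystatin C 1.03 mg/L, age 77 y,
#: weight 77 kg).
CREATININE_REF = 0.9
CYSTATIN_REF = 1.03
AGE_REF = 77.0
WEIGHT_REF = 77.0

STRUCTURAL_PARAM_NAMES = ("CL", "V1", "Q2", "V2", "Q3", "V3")


class InvalidParameterError(ValueError):
    """A structural parameter or covariate is outside its valid domain."""


@dataclass(frozen=True)
class StructuralParams:
    """Micro-constant parameterisation of a 2- or 3-compartment model.

    Parameters
    ----------
    CL : float
        Elimination clearance from the central compartment (L/min).
    V1 : float
        Central (sampled) volume of distribution (L).
    Q2, V2 : float
        Inter-compartmental clearance and volume of the first peripheral
        compartment (L/min, L).
    Q3, V3 : float, optional
        Second peripheral compartment; present iff the model has three
        compartments.

    Notes
    -----
    Volumes and CL must be strictly positive.  Inter-compartmental
    clearances may be zero, which disconnects the corresponding peripheral
    compartment (the mono-exponential limit).
    """

    CL: float
    V1: float
    Q2: float
    V2: float
    Q3: float | None = None
    V3: float | None = None

    def __post_init__(self) -> None:
        if not (self.CL > 0 and self.V1 > 0 and self.V2 > 0):
            raise InvalidParameterError(
                "CL, V1 and V2 must be strictly positive, got "
                f"CL={self.CL}, V1={self.V1}, V2={self.V2}"
            )
        if self.Q2 < 0:
            raise InvalidParameterError(f"Q2 must be non-negative, got {self.Q2}")
        if (self.Q3 is None) != (self.V3 is None):
            raise InvalidParameterError("Q3 and V3 must be supplied together")
        if self.Q3 is not None:
            if self.V3 <= 0:
                raise InvalidParameterError(f"V3 must be strictly positive, got {self.V3}")
            if self.Q3 < 0:
                raise InvalidParameterError(f"Q3 must be non-negative, got {self.Q3}")

    @property
    def n_compartments(self) -> int:
        return 2 if self.Q3 is None else 3

    @property
    def cl_ml_min(self) -> float:
        """Elimination clearance in the reporting unit mL/min."""
        return self.CL * 1000.0

    def as_dict(self) -> dict[str, float]:
        d = {"CL": self.CL, "V1": self.V1, "Q2": self.Q2, "V2": self.V2}
        if self.n_compartments == 3:
            d["Q3"] = self.Q3
            d["V3"] = self.V3
        return d

    def replace(self, **updates: float) -> "StructuralParams":
        d = self.as_dict()
        d.update(updates)
        return StructuralParams(**d)

    def rate_matrix(self) -> np.ndarray:
        """First-order rate matrix M such that dA/dt = M A for amounts A."""
        k10 = self.CL / self.V1
        k12 = self.Q2 / self.V1
        k21 = self.Q2 / self.V2
        if self.n_compartments == 2:
            return np.array([[-(k10 + k12), k21], [k12, -k21]])
        k13 = self.Q3 / self.V1
        k31 = self.Q3 / self.V3
        return np.array(
            [
                [-(k10 + k12 + k13), k21, k31],
                [k12, -k21, 0.0],
                [k13, 0.0, -k31],
            ]
        )


@dataclass(frozen=True)
class Covariates:
    """Subject-level covariates entering the clearance/volume model.

    sex is ``"male"`` or ``"female"``; height (m) is optional and only used
    for body-surface area.
    """

    age: float
    sex: Literal["male", "female"]
    weight: float
    creatinine: float
    cystatin_c: float
    height: float | None = None

    def __post_init__(self) -> None:
        if self.sex not in ("male", "female"):
            raise InvalidParameterError(f"sex must be 'male' or 'female', got {self.sex!r}")
        for name in ("age", "weight", "creatinine", "cystatin_c"):
            value = getattr(self, name)
            if not value > 0:
                raise InvalidParameterError(f"{name} must be strictly positive, got {value}")
        if self.height is not None and not self.height > 0:
            raise InvalidParameterError(f"height must be strictly positive, got {self.height}")

    @property
    def is_female(self) -> bool:
        return self.sex == "female"


@dataclass(frozen=True)
class CovariateCoefficients:
    """Power-law covariate model for clearance and central volume.

    Individual clearance is the typical clearance times power functions of
    creatinine, cystatin C, age and weight (each normalised to the cohort
    median) and a proportional shift for female sex; individual central
    volume scales with weight only::

        CL_i = typical_cl * (CR/0.9)^cr_exp * (CC/1.03)^cc_exp
               * (age/77)^age_exp * (weight/77)^weight_exp_cl
               * (1 + female_shift  if female)
        V1_i = typical_v1 * (weight/77)^weight_exp_v1
    """

    typical_cl: float
    cr_exp: float
    cc_exp: float
    age_exp: float
    weight_exp_cl: float
    female_shift: float
    typical_v1: float
    weight_exp_v1: float

    def __post_init__(self) -> None:
        if not (self.typical_cl > 0 and self.typical_v1 > 0):
            raise InvalidParameterError("typical_cl and typical_v1 must be strictly positive")
        if not self.female_shift > -1:
            raise InvalidParameterError(
                f"female_shift must exceed -1, got {self.female_shift}"
            )


def apply_covariates(
    coef: CovariateCoefficients, cov: Covariates
) -> tuple[float, float]:
    """Individual (CL_i, V1_i) in L/min and L from the covariate model."""
    cl = (
        coef.typical_cl
        * (cov.creatinine / CREATININE_REF) ** coef.cr_exp
        * (cov.cystatin_c / CYSTATIN_REF) ** coef.cc_exp
        * (cov.age / AGE_REF) ** coef.age_exp
        * (cov.weight / WEIGHT_REF) ** coef.weight_exp_cl
    )
    if cov.is_female:
        cl *= 1.0 + coef.female_shift
    v1 = coef.typical_v1 * (cov.weight / WEIGHT_REF) ** coef.weight_exp_v1
    return cl, v1


# -- analytic solution ------------------------------------------------------

_DEGENERATE_GAP = 1e-9
_PERTURB = 1e-8


def exponential_terms(params: StructuralParams) -> tuple[np.ndarray, np.ndarray]:
    """Decompose the unit-dose bolus response into a sum of exponentials.

    Returns ``(lam, w)`` such that the amount in the central compartment for
    a unit bolus is ``sum_k w[k] * exp(lam[k] * t)``.  Near-coincident
    eigenvalues (relative gap below 1e-9 with an ill-conditioned eigenvector
    matrix) are resolved by a symmetric 1e-8 relative perturbation of the
    peripheral volumes.
    """
    lam, vec = _eig_checked(params)
    a0 = np.zeros(params.n_compartments)
    a0[0] = 1.0
    w = vec[0, :] * np.linalg.solve(vec, a0)
    return lam.real, w.real


def _eig_checked(params: StructuralParams) -> tuple[np.ndarray, np.ndarray]:
    lam, vec = np.linalg.eig(params.rate_matrix())
    scale = np.max(np.abs(lam))
    if scale > 0:
        gaps = np.abs(lam[:, None] - lam[None, :])
        np.fill_diagonal(gaps, np.inf)
        if gaps.min() / scale < _DEGENERATE_GAP and np.linalg.cond(vec) > 1e6:
            updates = {"V2": params.V2 * (1.0 + _PERTURB)}
            if params.n_compartments == 3:
                updates["V3"] = params.V3 * (1.0 - _PERTURB)
            lam, vec = np.linalg.eig(params.replace(**updates).rate_matrix())
    return lam, vec


def predict_concentration(
    params: StructuralParams, dose: float, times: np.ndarray | float
) -> np.ndarray:
    """Central-compartment concentration (µg/mL) after an IV bolus.

    The dose (mg) is placed in the central compartment at t = 0 and the
    linear mass-balance system is solved in closed form; mg/L output is
    numerically identical to µg/mL.
    """
    if not dose > 0:
        raise InvalidParameterError(f"dose must be strictly positive, got {dose}")
    t = np.atleast_1d(np.asarray(times, dtype=float))
    if np.any(t < 0):
        raise InvalidParameterError("times must be non-negative")
    lam, w = exponential_terms(params)
    amounts = np.exp(t[:, None] * lam[None, :]) @ w
    return dose / params.V1 * amounts


def auc_zero_inf(params: StructuralParams, dose: float) -> float:
    """Analytic area under C(t) from 0 to infinity (µg·min/mL).

    For any linear mammillary model this equals dose/CL; computed here from
    the exponential terms as an internal cross-check quantity.
    """
    lam, w = exponential_terms(params)
    return float(dose / params.V1 * np.sum(-w / lam))


# -- clinical formulas ------------------------------------------------------


def bsa_dubois(height: float, weight: float) -> float:
    """Du Bois & Du Bois body surface area (m²) from height (m), weight (kg)."""
    if not (height > 0 and weight > 0):
        raise InvalidParameterError("height and weight must be strictly positive")
    return 0.20247 * height**0.725 * weight**0.425


class ConfigurationError(RuntimeError):
    """A required runtime configuration (e.g. eGFR coefficients) is missing."""


_EGFR_KEYS = ("scale", "creatinine_exp", "cystatin_exp", "age_exp", "female_factor")


def egfr_bis2(cov: Covariates, coefficients: Mapping[str, float]) -> float:
    """Creatinine + cystatin C estimated GFR (mL/min/1.73 m²).

    Evaluates ``scale * CR^creatinine_exp * CC^cystatin_exp * age^age_exp``
    times ``female_factor`` for women.  The coefficients of the published
    BIS2 equation are distributed as a config file
    (:func:`iohexolpk.population.load_bis2_coefficients`), not as code
    constants.
    """
    missing = [k for k in _EGFR_KEYS if k not in coefficients]
    if missing:
        raise ConfigurationError(
            f"eGFR coefficient config is missing keys: {', '.join(missing)}"
        )
    value = (
        coefficients["scale"]
        * cov.creatinine ** coefficients["creatinine_exp"]
        * cov.cystatin_c ** coefficients["cystatin_exp"]
        * cov.age ** coefficients["age_exp"]
    )
    if cov.is_female:
        value *= coefficients["female_factor"]
    return float(value)
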