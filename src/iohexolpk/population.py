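"""Population model containers: fixed effects, random-effect structure, residual error.

A :class:`PopulationModel` bundles the typical structural parameters, the
random-effect (RE) mask with its covariance Ω, the residual-error model σ and
optionally the covariate model.  Individual parameters arise as
``PK_i = PK_typical * exp(eta_i)`` for every parameter carrying a random
effect; parameters outside the mask stay at their (covariate-adjusted)
typical value.

Model parameter files are YAML with blocks ``theta``, ``omega``, ``sigma``
and ``model`` (compartments, re_mask, covariates_enabled).  The packaged
files under ``iohexolpk/models/`` are synthetic stand-ins constructed from
typical iohexol pharmacokinetics in elderly adults; see each file's header.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
import yaml

from .pk_models import (
    Covariates,
    CovariateCoefficients,
    InvalidParameterError,
    StructuralParams,
    STRUCTURAL_PARAM_NAMES,
    apply_covariates,
)

__all__ = [
    "ResidualModel",
    "PopulationModel",
    "individual_params",
    "load_model",
    "save_model",
    "load_bundled_model",
    "bundled_model_names",
    "load_bis2_coefficients",
]


@dataclass(frozen=True)
class ResidualModel:
    """Residual (unexplained) error model on observed concentrations.

    kind ``"proportional"``: sd = sigma_prop * IPRED;
    ``"additive"``: sd = sigma_add (µg/mL);
    ``"combined"``: variances add.
    """

    kind: str = "proportional"
    sigma_prop: float = 0.0
    sigma_add: float = 0.0

    def __post_init__(self) -> None:
        if self.kind not in ("proportional", "additive", "combined"):
            raise InvalidParameterError(f"unknown residual model kind {self.kind!r}")
        if self.sigma_prop < 0 or self.sigma_add < 0:
            raise InvalidParameterError("residual SDs must be non-negative")
        if self.kind == "proportional" and self.sigma_prop <= 0:
            raise InvalidParameterError("proportional residual model needs sigma_prop > 0")
        if self.kind == "additive" and self.sigma_add <= 0:
            raise InvalidParameterError("additive residual model needs sigma_add > 0")
        if self.kind == "combined" and self.sigma_prop + self.sigma_add <= 0:
            raise InvalidParameterError("combined residual model needs a positive component")

    def variance(self, ipred: np.ndarray) -> np.ndarray:
        """Per-observation residual variance σ_ij² given predictions."""
        ipred = np.asarray(ipred, dtype=float)
        var = np.zeros_like(ipred)
        if self.kind in ("proportional", "combined"):
            var = var + (self.sigma_prop * ipred) ** 2
        if self.kind in ("additive", "combined"):
            var = var + self.sigma_add**2
        return var


@dataclass(frozen=True)
class PopulationModel:
    """A population PK model: θ typicals, RE mask + Ω, σ, optional covariates."""

    structural: StructuralParams
    re_mask: tuple[str, ...]
    omega: np.ndarray
    residual: ResidualModel
    covariates: CovariateCoefficients | None = None
    name: str = "unnamed"

    def __post_init__(self) -> None:
        valid = STRUCTURAL_PARAM_NAMES[: 2 * self.structural.n_compartments]
        for p in self.re_mask:
            if p not in valid:
                raise InvalidParameterError(f"random effect on unknown parameter {p!r}")
        omega = np.atleast_2d(np.asarray(self.omega, dtype=float))
        if omega.shape != (len(self.re_mask), len(self.re_mask)):
            raise InvalidParameterError(
                f"omega shape {omega.shape} does not match RE mask {self.re_mask}"
            )
        if not np.allclose(omega, omega.T):
            raise InvalidParameterError("omega must be symmetric")
        object.__setattr__(self, "omega", omega)

    @property
    def n_random_effects(self) -> int:
        return len(self.re_mask)

    def omega_inverse(self) -> np.ndarray:
        try:
            return np.linalg.inv(self.omega)
        except np.linalg.LinAlgError as exc:
            raise InvalidParameterError("omega is singular") from exc

    def omega_cholesky(self) -> np.ndarray:
        """Lower Cholesky factor of Ω; zero matrix if Ω is exactly zero."""
        if np.all(self.omega == 0):
            return np.zeros_like(self.omega)
        try:
            return np.linalg.cholesky(self.omega)
        except np.linalg.LinAlgError as exc:
            raise InvalidParameterError("omega is not positive definite") from exc

    def typical_params(self, cov: Covariates | None = None) -> StructuralParams:
        """Covariate-adjusted typical structural parameters for one subject."""
        if self.covariates is None:
            return self.structural
        if cov is None:
            raise InvalidParameterError(
                f"model {self.name!r} has a covariate model; covariates are required"
            )
        cl, v1 = apply_covariates(self.covariates, cov)
        return self.structural.replace(CL=cl, V1=v1)

    def with_structural(self, structural: StructuralParams) -> "PopulationModel":
        return replace(self, structural=structural)


def individual_params(
    pop: PopulationModel,
    eta: np.ndarray,
    cov: Covariates | None = None,
) -> StructuralParams:
    """Individual parameters: typical values times exp(η) on masked parameters."""
    eta = np.asarray(eta, dtype=float)
    if eta.shape != (pop.n_random_effects,):
        raise InvalidParameterError(
            f"eta has shape {eta.shape}, expected ({pop.n_random_effects},) "
            f"for RE mask {pop.re_mask}"
        )
    base = pop.typical_params(cov)
    updates = {
        p: getattr(base, p) * np.exp(e) for p, e in zip(pop.re_mask, eta)
    }
    return base.replace(**updates)


# -- model file I/O ---------------------------------------------------------

_COVARIATE_KEYS = (
    "cr_exp",
    "cc_exp",
    "age_exp",
    "weight_exp_cl",
    "female_shift",
    "weight_exp_v1",
)


def _model_from_dict(doc: dict, name: str) -> PopulationModel:
    model = doc["model"]
    theta = doc["theta"]
    n_cmt = int(model["compartments"])
    if n_cmt not in (2, 3):
        raise InvalidParameterError(f"compartments must be 2 or 3, got {n_cmt}")
    struct_keys = STRUCTURAL_PARAM_NAMES[: 2 * n_cmt]
    structural = StructuralParams(**{k: float(theta[k]) for k in struct_keys})
    covariates = None
    if model.get("covariates_enabled", False):
        covariates = CovariateCoefficients(
            typical_cl=float(theta["CL"]),
            typical_v1=float(theta["V1"]),
            **{k: float(theta[k]) for k in _COVARIATE_KEYS},
        )
    sigma = doc.get("sigma", {})
    residual = ResidualModel(
        kind=sigma.get("kind", "proportional"),
        sigma_prop=float(sigma.get("prop", 0.0)),
        sigma_add=float(sigma.get("add", 0.0)),
    )
    return PopulationModel(
        structural=structural,
        re_mask=tuple(model["re_mask"]),
        omega=np.asarray(doc["omega"], dtype=float),
        residual=residual,
        covariates=covariates,
        name=doc.get("name", name),
    )


def load_model(path: str | Path) -> PopulationModel:
    """Load a population model from a YAML parameter file."""
    path = Path(path)
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    return _model_from_dict(doc, name=path.stem)


def save_model(pop: PopulationModel, path: str | Path) -> None:
    theta = pop.structural.as_dict()
    if pop.covariates is not None:
        for k in _COVARIATE_KEYS:
            theta[k] = getattr(pop.covariates, k)
    doc = {
        "name": pop.name,
        "model": {
            "compartments": pop.structural.n_compartments,
            "re_mask": list(pop.re_mask),
            "covariates_enabled": pop.covariates is not None,
        },
        "theta": {k: float(v) for k, v in theta.items()},
        "omega": [[float(v) for v in row] for row in pop.omega],
        "sigma": {
            "kind": pop.residual.kind,
            "prop": pop.residual.sigma_prop,
            "add": pop.residual.sigma_add,
        },
    }
    with open(path, "w") as fh:
        yaml.safe_dump(doc, fh, sort_keys=False)


def _bundled(name: str):
    return importlib.resources.files("iohexolpk") / "models" / name


def bundled_model_names() -> list[str]:
    """Names of the packaged (synthetic) population model files."""
    root = importlib.resources.files("iohexolpk") / "models"
    return sorted(
        p.name.removesuffix(".yaml")
        for p in root.iterdir()
        if p.name.endswith(".yaml") and p.name != "bis2.yaml"
    )


def load_bundled_model(name: str) -> PopulationModel:
    """Load one of the packaged synthetic population models by short name.

    Available: ``cmt2_full``, ``cmt2_limited``, ``cmt3_full``,
    ``cmt3_limited``, ``cmt3_limited_cov`` (each stored as
    ``<name>_synthetic.yaml``).
    """
    fname = name if name.endswith(".yaml") else f"{name}_synthetic.yaml"
    resource = _bundled(fname)
    if not resource.is_file():
        raise FileNotFoundError(
            f"no bundled model {name!r}; available: {bundled_model_names()}"
        )
    doc = yaml.safe_load(resource.read_text())
    return _model_from_dict(doc, name=fname.removesuffix(".yaml"))


def load_bis2_coefficients(path: str | Path | None = None) -> dict[str, float]:
    """Coefficients of the BIS2 eGFR equation from config (packaged default)."""
    if path is None:
        text = _bundled("bis2.yaml").read_text()
    else:
        text = Path(path).read_text()
    doc = yaml.safe_load(text)
    return {k: float(v) for k, v in doc["coefficients"].items()}
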