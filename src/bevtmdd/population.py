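"""Population layer: fixed effects, covariates and random effects.

Individual parameters follow the log-normal inter-individual variability
(IIV) model P_i = P_pop * (covariate factors) * exp(eta_i), with eta_i ~
N(0, omega^2) per parameter.  Covariate factors come in three forms:

* linear, centred at the study median:  1 + theta * (Cov - Cov_med)
* power:  (Cov / Cov_med)^k  (allometric body-weight scaling uses fixed
  exponents 0.75 for clearances and 1 for volumes)
* linear on a categorical indicator:  1 + theta * I[Cov == level]

Residual error models per analyte: proportional, additive or combined on
the natural scale, or additive on the log scale (the convention for the
simultaneous drug+target fit).
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass
from typing import Mapping, Sequence

from .dataset import Analyte, PatientCovariates
from .structural import PKParameters, TMDDParameters
from .units import DEFAULT_MOLAR_CONSTANTS, MolarConstants

__all__ = [
    "RelationForm",
    "CovariateRelation",
    "ErrorModel",
    "ResidualErrorSpec",
    "StructuralModel",
    "PopulationModelSpec",
    "individual_parameters",
    "residual_distribution",
    "iiv_cv_percent",
    "allometric_relations",
]

PK_PARAM_NAMES = ("CL", "V1", "Q", "V2")
TMDD_PARAM_NAMES = ("CL", "V1", "Q", "V2", "CL_RC", "BM0", "kout", "Kss")
CLEARANCE_PARAMS = ("CL", "Q", "CL_RC")
VOLUME_PARAMS = ("V1", "V2")


class RelationForm(enum.Enum):
    LINEAR_CENTERED = "linear_centered"
    POWER = "power"
    LINEAR_CATEGORICAL = "linear_categorical"


@dataclass(frozen=True)
class CovariateRelation:
    """One parameter-covariate relation.

    ``value`` is the coefficient theta (linear forms) or the exponent k
    (power form).  ``reference`` is the centring value Cov_med for
    continuous covariates.  ``level`` selects the indicator category for
    LINEAR_CATEGORICAL (wild type / reference level gets factor 1).
    ``fixed`` marks coefficients that are not estimated (e.g. allometric
    exponents)."""

    parameter: str
    covariate: str
    form: RelationForm
    value: float
    reference: float | None = None
    level: str | None = None
    fixed: bool = False

    def __post_init__(self) -> None:
        if self.form is RelationForm.POWER:
            if self.reference is None or self.reference <= 0:
                raise ValueError("POWER relations need a positive reference value")
        if self.form is RelationForm.LINEAR_CENTERED and self.reference is None:
            raise ValueError("LINEAR_CENTERED relations need a reference value")
        if self.form is RelationForm.LINEAR_CATEGORICAL and self.level is None:
            raise ValueError("LINEAR_CATEGORICAL relations need a level")

    @property
    def name(self) -> str:
        suffix = f"_{self.level}" if self.level else ""
        return f"{self.parameter}~{self.covariate}{suffix}"

    def factor(self, covariates: PatientCovariates, value: float | None = None) -> float:
        """Multiplicative factor for one subject; ``value`` overrides the
        stored coefficient (used during estimation)."""
        coef = self.value if value is None else value
        if self.form is RelationForm.LINEAR_CATEGORICAL:
            indicator = 1.0 if getattr(covariates, self.covariate) == self.level else 0.0
            return 1.0 + coef * indicator
        cov = covariates.numeric(self.covariate)
        if self.form is RelationForm.POWER:
            return (cov / self.reference) ** coef
        return 1.0 + coef * (cov - self.reference)


def allometric_relations(
    parameters: Sequence[str],
    reference_weight: float = 70.0,
) -> list[CovariateRelation]:
    """Fixed-exponent allometric weight scaling: 0.75 on clearance
    parameters, 1.0 on volume parameters."""
    rels = []
    for p in parameters:
        if p in CLEARANCE_PARAMS:
            k = 0.75
        elif p in VOLUME_PARAMS:
            k = 1.0
        else:
            raise ValueError(f"no allometric convention for parameter {p!r}")
        rels.append(CovariateRelation(
            parameter=p, covariate="weight", form=RelationForm.POWER,
            value=k, reference=reference_weight, fixed=True,
        ))
    return rels


class ErrorModel(enum.Enum):
    PROPORTIONAL = "proportional"
    ADDITIVE = "additive"
    COMBINED = "combined"
    ADDITIVE_LOG = "additive_log"


@dataclass(frozen=True)
class ResidualErrorSpec:
    """Residual error for one analyte.  ``sigma`` is the proportional (or
    log-scale) SD; ``sigma_add`` the additive SD, used by ADDITIVE and
    COMBINED."""

    model: ErrorModel
    sigma: float
    sigma_add: float = 0.0

    def __post_init__(self) -> None:
        if self.model is ErrorModel.ADDITIVE:
            if not self.sigma_add > 0:
                raise ValueError("ADDITIVE error needs sigma_add > 0")
        elif not self.sigma > 0:
            raise ValueError("residual sigma must be > 0")
        if self.model is ErrorModel.COMBINED and not self.sigma_add > 0:
            raise ValueError("COMBINED error needs sigma_add > 0")


class StructuralModel(enum.Enum):
    LINEAR_PK = "linear_pk"
    QSS_TMDD = "qss_tmdd"


@dataclass(frozen=True)
class PopulationModelSpec:
    """Full population model: structural selector, typical values (theta,
    natural scale; concentrations in nM), diagonal IIV variances omega2,
    residual error per analyte, covariate relations, molar masses."""

    structural: StructuralModel
    theta: Mapping[str, float]
    omega2: Mapping[str, float]
    error: Mapping[Analyte, ResidualErrorSpec]
    relations: tuple[CovariateRelation, ...] = ()
    mw: MolarConstants = DEFAULT_MOLAR_CONSTANTS

    def __post_init__(self) -> None:
        names = self.parameter_names
        for p, w2 in self.omega2.items():
            if p not in names:
                raise ValueError(f"omega2 references unknown parameter {p!r}")
            if w2 < 0:
                raise ValueError(f"omega2[{p}] must be >= 0, got {w2}")
        for rel in self.relations:
            if rel.parameter not in names:
                raise ValueError(f"relation {rel.name} references unknown parameter")
        for p in self.theta:
            if p not in names:
                raise ValueError(f"theta references unknown parameter {p!r}")
        missing = [p for p in names if p not in self.theta and p != "CL_RC"]
        if missing:
            raise ValueError(f"theta missing parameters: {missing}")

    @property
    def parameter_names(self) -> tuple[str, ...]:
        return (
            PK_PARAM_NAMES if self.structural is StructuralModel.LINEAR_PK
            else TMDD_PARAM_NAMES
        )

    @property
    def eta_names(self) -> tuple[str, ...]:
        """Parameters carrying IIV, in canonical order."""
        return tuple(p for p in self.parameter_names if self.omega2.get(p, 0.0) > 0)

    @property
    def clrc_tied(self) -> bool:
        """True when the complex clearance is tied to CL (the default:
        sparse data rarely support estimating it separately)."""
        return self.structural is StructuralModel.QSS_TMDD and "CL_RC" not in self.theta

    def with_theta(self, theta: Mapping[str, float]) -> "PopulationModelSpec":
        return PopulationModelSpec(
            self.structural, dict(theta), dict(self.omega2), dict(self.error),
            self.relations, self.mw,
        )


def individual_parameters(
    spec: PopulationModelSpec,
    theta: Mapping[str, float],
    eta: Mapping[str, float],
    covariates: PatientCovariates,
    relation_values: Mapping[str, float] | None = None,
) -> PKParameters | TMDDParameters:
    """Resolve one subject's structural parameters:
    P_i = theta_P * prod(covariate factors) * exp(eta_P).

    ``relation_values`` overrides estimated covariate coefficients by
    relation name.  A linear factor driving any parameter non-positive
    raises (flagged, never clipped)."""
    values: dict[str, float] = {}
    for p in spec.parameter_names:
        if p == "CL_RC" and spec.clrc_tied:
            continue
        x = float(theta[p])
        for rel in spec.relations:
            if rel.parameter != p:
                continue
            override = None
            if relation_values is not None and rel.name in relation_values:
                override = relation_values[rel.name]
            f = rel.factor(covariates, override)
            if f <= 0:
                raise ValueError(
                    f"covariate relation {rel.name} gives non-positive factor {f}"
                )
            x *= f
        x *= math.exp(float(eta.get(p, 0.0)))
        values[p] = x
    if spec.structural is StructuralModel.LINEAR_PK:
        return PKParameters(**values)
    if spec.clrc_tied:
        values["CL_RC"] = values["CL"]
    return TMDDParameters(**values)


def residual_distribution(
    spec: PopulationModelSpec, analyte: Analyte, prediction: float
) -> tuple[float, float, bool]:
    """Mean and variance of one observation on its likelihood scale.

    Returns ``(mean, variance, log_scale)``; when ``log_scale`` is True the
    observation must be log-transformed before comparison."""
    err = spec.error[analyte]
    f = float(prediction)
    if err.model is ErrorModel.ADDITIVE_LOG:
        if f <= 0:
            raise ValueError(
                f"log-scale residual model needs prediction > 0, got {f}"
            )
        return math.log(f), err.sigma**2, True
    if err.model is ErrorModel.PROPORTIONAL:
        return f, (err.sigma * f) ** 2, False
    if err.model is ErrorModel.ADDITIVE:
        return f, err.sigma_add**2, False
    # COMBINED
    return f, err.sigma_add**2 + (err.sigma * f) ** 2, False


def iiv_cv_percent(omega2: float, exact: bool = False) -> float:
    """IIV magnitude as CV%.

    By default the reporting convention 100*omega (accurate for small
    omega); with ``exact=True`` the log-normal CV
    100*sqrt(exp(omega^2)-1)."""
    if omega2 < 0:
        raise ValueError("omega2 must be >= 0")
    if exact:
        return 100.0 * math.sqrt(math.expm1(omega2))
    return 100.0 * math.sqrt(omega2)
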