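"""Structural pharmacokinetic model for vancomycin in NICU neonates.

Disposition is a one-compartment model with zero-order (constant-rate
infusion) input and first-order elimination, the standard description of
vancomycin kinetics in neonates when only trough/peak sampling is
available.  Clearance ``CL`` (L/h) and apparent volume ``V`` (L) carry
covariate effects and log-normal inter-individual variability:

    P_i = P_TV * prod_c (x_c / x_ref)^theta_c * prod_b exp(theta_b * I_b) * exp(eta_i)

with ``eta_i ~ N(0, omega^2)``.  Continuous covariates (weight, serum
creatinine, daily fluid input, ...) enter as centred power terms;
binary covariates (diuretic use, ...) as exponential indicators.

Residual variability supports additive, proportional and combined
error models on the observation scale ``Y = F*(1+eps1) + eps2``.

The default ("final") covariate model shipped here is the NICU neonatal
vancomycin model with weight, serum creatinine, daily fluid input and
diuretic co-medication on CL and weight on V:

    CL (L/h) = 0.14 * (WT/2.12)^1.13 * (Scr/30.52)^-0.15
                    * (DFI/367.18)^0.14 * exp(-0.20 * DA) * exp(eta_CL)
    V  (L)   = 1.04 * (WT/2.12)^1.07

All times are hours since each subject's first dose; amounts mg;
concentrations mg/L; weight kg; creatinine umol/L; fluid input mL/day.
"""

from __future__ import annotations

import math
from collections import namedtuple
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np

__all__ = [
    "CALIBRATION_RANGE",
    "WT_REF",
    "SCR_REF",
    "DFI_REF",
    "ValidationError",
    "DomainError",
    "DoseEvent",
    "Observation",
    "Covariates",
    "Subject",
    "ParameterSet",
    "CovariateRelation",
    "ModelSpec",
    "PKParams",
    "individual_params",
    "typical_params",
    "concentration",
    "residual_variance",
    "auc24_at_steady_state",
    "percent_cv",
    "final_model_spec",
    "final_model_parameters",
    "base_model_spec",
    "base_model_inits",
]

#: Assay calibration range (mg/L); observations outside it are flagged
#: excluded and never enter estimation.
CALIBRATION_RANGE = (2.0, 50.0)

#: Default covariate centering constants of the final model.
WT_REF = 2.12     # kg
SCR_REF = 30.52   # umol/L
DFI_REF = 367.18  # mL/day


class ValidationError(ValueError):
    """Malformed input (missing covariate, bad column, bad enum...)."""


class DomainError(ValueError):
    """Numerically out-of-domain input (negative time, non-positive covariate...)."""


# ---------------------------------------------------------------------------
# domain containers
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class DoseEvent:
    """One intravenous infusion: start (h since first dose), amount (mg), duration (h)."""

    start_time: float
    amount: float
    duration: float = 1.0

    def __post_init__(self) -> None:
        if not self.amount > 0:
            raise ValidationError(f"dose amount must be > 0, got {self.amount}")
        if not self.duration > 0:
            raise ValidationError(f"infusion duration must be > 0, got {self.duration}")
        if self.start_time < 0:
            raise ValidationError(f"dose start_time must be >= 0, got {self.start_time}")

    @property
    def rate(self) -> float:
        """Zero-order input rate R0 (mg/h)."""
        return self.amount / self.duration

    @property
    def end_time(self) -> float:
        return self.start_time + self.duration


@dataclass(frozen=True)
class Observation:
    """A measured concentration (mg/L) at ``time`` hours since first dose.

    ``kind`` is one of ``trough`` / ``peak`` / ``other``; ``excluded``
    marks records outside the assay calibration range, which are kept
    for bookkeeping but never fitted.
    """

    time: float
    concentration: float
    kind: str = "other"
    excluded: bool = False

    def __post_init__(self) -> None:
        if self.time < 0:
            raise ValidationError(f"observation time must be >= 0, got {self.time}")
        if not self.concentration > 0:
            raise ValidationError(
                f"concentration must be > 0, got {self.concentration}"
            )
        if self.kind not in ("trough", "peak", "other"):
            raise ValidationError(f"unknown observation kind {self.kind!r}")


def within_calibration(conc: float, calibration=CALIBRATION_RANGE) -> bool:
    lo, hi = calibration
    return lo <= conc <= hi


class Covariates(dict):
    """Covariate vector for one neonate.

    Required keys: WT (kg), SCR (umol/L), DFI (mL/day), DA (diuretic use,
    0/1).  Optional screening covariates (PMA, PM, SEX, ALB, ALT, AST,
    BUN, DUV, NCIS, RS, PTZ, HA, VAA) may be present as well.
    """

    REQUIRED = ("WT", "SCR", "DFI", "DA")
    POSITIVE = ("WT", "SCR", "DFI")
    BINARY = ("DA", "SEX", "PM", "RS", "PTZ", "HA", "VAA")

    def __init__(self, **values: float) -> None:
        for key in self.REQUIRED:
            if key not in values:
                raise ValidationError(f"missing required covariate {key!r}")
        for key in self.POSITIVE:
            if key in values and not values[key] > 0:
                raise DomainError(f"covariate {key} must be > 0, got {values[key]}")
        for key in self.BINARY:
            if key in values and values[key] not in (0, 1, 0.0, 1.0):
                raise ValidationError(f"covariate {key} must be 0/1, got {values[key]}")
        super().__init__(values)


@dataclass(frozen=True)
class Subject:
    """One neonate: dose history, observations and a covariate vector."""

    id: str
    doses: tuple[DoseEvent, ...]
    observations: tuple[Observation, ...]
    covariates: Covariates

    def __post_init__(self) -> None:
        object.__setattr__(self, "doses", tuple(self.doses))
        object.__setattr__(self, "observations", tuple(self.observations))
        if len(self.doses) == 0:
            raise ValidationError(f"subject {self.id}: at least one dose required")

    @property
    def active_observations(self) -> tuple[Observation, ...]:
        return tuple(o for o in self.observations if not o.excluded)


@dataclass
class ParameterSet:
    """Fixed effects, random-effect variances, residual parameters.

    ``theta`` maps ``tvCL``/``tvV`` plus one coefficient per covariate
    relation (keyed ``<COV>_on_<PARAM>``); ``omega`` maps parameter name
    to the *variance* of its eta; ``sigma`` holds residual SDs under
    keys ``proportional`` (unitless) and/or ``additive`` (mg/L).
    """

    theta: dict = field(default_factory=dict)
    omega: dict = field(default_factory=dict)
    sigma: dict = field(default_factory=dict)

    def validate(self) -> None:
        if not self.theta.get("tvCL", 1.0) > 0:
            raise ValidationError("tvCL must be > 0")
        if not self.theta.get("tvV", 1.0) > 0:
            raise ValidationError("tvV must be > 0")
        for k, v in self.omega.items():
            if v < 0:
                raise ValidationError(f"omega[{k}] must be >= 0")
        for k, v in self.sigma.items():
            if v < 0:
                raise ValidationError(f"sigma[{k}] must be >= 0")
        if self.sigma and not any(v > 0 for v in self.sigma.values()):
            raise ValidationError("at least one sigma component must be > 0")

    def omega_sd(self, param: str) -> float:
        return math.sqrt(self.omega.get(param, 0.0))

    def copy(self) -> "ParameterSet":
        return ParameterSet(dict(self.theta), dict(self.omega), dict(self.sigma))

    def to_dict(self) -> dict:
        return {"theta": dict(self.theta), "omega": dict(self.omega), "sigma": dict(self.sigma)}

    @classmethod
    def from_dict(cls, d: Mapping) -> "ParameterSet":
        return cls(dict(d["theta"]), dict(d["omega"]), dict(d["sigma"]))


@dataclass(frozen=True)
class CovariateRelation:
    """One covariate-to-parameter link.

    ``power`` form multiplies the typical value by ``(x/reference)^coef``;
    ``exponential_indicator`` by ``exp(coef * x)`` for a 0/1 covariate.
    """

    covariate: str
    parameter: str              # 'CL' or 'V'
    form: str = "power"         # 'power' | 'exponential_indicator'
    reference: float | None = None

    def __post_init__(self) -> None:
        if self.parameter not in ("CL", "V"):
            raise ValidationError(f"relation parameter must be CL or V, got {self.parameter!r}")
        if self.form not in ("power", "exponential_indicator"):
            raise ValidationError(f"unknown covariate form {self.form!r}")
        if self.form == "power":
            if self.reference is None or not self.reference > 0:
                raise ValidationError(
                    f"power form for {self.covariate} needs a positive centering constant"
                )

    @property
    def name(self) -> str:
        return f"{self.covariate}_on_{self.parameter}"

    def to_dict(self) -> dict:
        return {
            "covariate": self.covariate,
            "parameter": self.parameter,
            "form": self.form,
            "reference": self.reference,
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "CovariateRelation":
        return cls(d["covariate"], d["parameter"], d.get("form", "power"), d.get("reference"))


@dataclass(frozen=True)
class ModelSpec:
    """Structural + stochastic model choice: residual model, which
    parameters carry inter-individual variability, and the covariate map."""

    residual_model: str = "proportional"   # 'additive' | 'proportional' | 'combined'
    iiv_parameters: tuple[str, ...] = ("CL",)
    relations: tuple[CovariateRelation, ...] = ()

    def __post_init__(self) -> None:
        if self.residual_model not in ("additive", "proportional", "combined"):
            raise ValidationError(f"unknown residual model {self.residual_model!r}")
        object.__setattr__(self, "iiv_parameters", tuple(self.iiv_parameters))
        object.__setattr__(self, "relations", tuple(self.relations))
        for p in self.iiv_parameters:
            if p not in ("CL", "V"):
                raise ValidationError(f"IIV parameter must be CL or V, got {p!r}")
        names = [r.name for r in self.relations]
        if len(set(names)) != len(names):
            raise ValidationError("duplicate covariate relations in ModelSpec")

    @property
    def theta_names(self) -> tuple[str, ...]:
        return ("tvCL", "tvV") + tuple(r.name for r in self.relations)

    @property
    def sigma_names(self) -> tuple[str, ...]:
        return {
            "additive": ("additive",),
            "proportional": ("proportional",),
            "combined": ("proportional", "additive"),
        }[self.residual_model]

    def with_relations(self, *relations: CovariateRelation) -> "ModelSpec":
        return replace(self, relations=self.relations + tuple(relations))

    def without_relations(self, *relations: CovariateRelation) -> "ModelSpec":
        drop = {r.name for r in relations}
        return replace(self, relations=tuple(r for r in self.relations if r.name not in drop))

    def to_dict(self) -> dict:
        return {
            "residual_model": self.residual_model,
            "iiv_parameters": list(self.iiv_parameters),
            "relations": [r.to_dict() for r in self.relations],
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "ModelSpec":
        return cls(
            d.get("residual_model", "proportional"),
            tuple(d.get("iiv_parameters", ("CL",))),
            tuple(CovariateRelation.from_dict(r) for r in d.get("relations", ())),
        )


PKParams = namedtuple("PKParams", ["CL", "V"])


# ---------------------------------------------------------------------------
# model evaluation
# ---------------------------------------------------------------------------

def typical_params(theta: Mapping, covariates: Mapping, spec: ModelSpec):
    """Typical (eta = 0) CL and V for one covariate vector or arrays of them.

    Accepts scalar covariate values or equally-shaped numpy arrays and
    broadcasts; returns ``PKParams(CL, V)``.
    """
    cl = np.asarray(theta["tvCL"], dtype=float)
    v = np.asarray(theta["tvV"], dtype=float)
    cl, v = np.broadcast_arrays(cl.copy(), v.copy())
    cl = np.array(cl, dtype=float)
    v = np.array(v, dtype=float)
    for rel in spec.relations:
        if rel.covariate not in covariates:
            raise ValidationError(f"missing required covariate {rel.covariate!r}")
        x = np.asarray(covariates[rel.covariate], dtype=float)
        coef = theta[rel.name]
        if rel.form == "power":
            if np.any(x <= 0):
                raise DomainError(f"covariate {rel.covariate} must be > 0 for power form")
            fac = (x / rel.reference) ** coef
        else:
            fac = np.exp(coef * x)
        if rel.parameter == "CL":
            cl = cl * fac
        else:
            v = v * fac
    cl, v = np.broadcast_arrays(cl, v)
    if cl.ndim == 0:
        return PKParams(float(cl), float(v))
    return PKParams(cl, v)


def individual_params(theta: Mapping, eta: Mapping, cov: Mapping, spec: ModelSpec) -> PKParams:
    """Individual CL (L/h) and V (L): typical values times ``exp(eta)``.

    ``eta`` maps parameter name ('CL', 'V') to its random effect; absent
    keys mean eta = 0.
    """
    cl, v = typical_params(theta, cov, spec)
    cl = cl * math.exp(float(eta.get("CL", 0.0)))
    v = v * math.exp(float(eta.get("V", 0.0)))
    if not (np.all(cl > 0) and np.all(v > 0)):
        raise DomainError("individual CL and V must be strictly positive")
    return PKParams(cl, v)


def concentration(t, doses: Sequence[DoseEvent], CL: float, V: float):
    """Concentration (mg/L) at time(s) ``t`` by exact superposition.

    Each infusion contributes the analytic one-compartment solution with
    elimination rate ``k_e = CL/V``: during the infusion
    ``(R0/CL)(1 - exp(-k_e dt))``, afterwards that value at infusion end
    decayed exponentially.  Linear kinetics make the sum exact.
    """
    if not (CL > 0 and V > 0):
        raise DomainError("CL and V must be > 0")
    t_arr = np.asarray(t, dtype=float)
    if np.any(t_arr < 0):
        raise DomainError("time must be >= 0")
    ke = CL / V
    out = np.zeros_like(t_arr, dtype=float)
    for d in doses:
        dt = t_arr - d.start_time
        te = np.clip(np.minimum(dt, d.duration), 0.0, None)
        after = np.clip(dt - d.duration, 0.0, None)
        out += (d.rate / CL) * (-np.expm1(-ke * te)) * np.exp(-ke * after)
    if out.ndim == 0:
        return float(out)
    return out


def residual_variance(f, sigma: Mapping, residual_model: str):
    """Residual variance ((mg/L)^2) at prediction ``f`` under the error model."""
    f_arr = np.asarray(f, dtype=float)
    if residual_model == "additive":
        var = np.full_like(f_arr, sigma["additive"] ** 2)
    elif residual_model == "proportional":
        var = f_arr ** 2 * sigma["proportional"] ** 2
    elif residual_model == "combined":
        var = f_arr ** 2 * sigma["proportional"] ** 2 + sigma["additive"] ** 2
    else:
        raise ValidationError(f"unknown residual model {residual_model!r}")
    if var.ndim == 0:
        return float(var)
    return var


def auc24_at_steady_state(daily_dose: float, CL: float) -> float:
    """Steady-state 24-h AUC (mg*h/L) of a maintained daily dose: dose/CL."""
    if not CL > 0:
        raise DomainError("CL must be > 0")
    if daily_dose < 0:
        raise DomainError("daily dose must be >= 0")
    return daily_dose / CL


def percent_cv(omega_sd: float, convention: str = "sd") -> float:
    """Report an eta SD as %CV.

    ``sd``: 100*omega (the Phoenix-style convention used by default);
    ``lognormal``: 100*sqrt(exp(omega^2)-1).  For omega around 0.05 the
    two agree to four decimals.
    """
    if convention == "sd":
        return 100.0 * omega_sd
    if convention == "lognormal":
        return 100.0 * math.sqrt(math.expm1(omega_sd ** 2))
    raise ValidationError(f"unknown %CV convention {convention!r}")


# ---------------------------------------------------------------------------
# reference model builders
# ---------------------------------------------------------------------------

def final_model_spec(wt_ref: float = WT_REF, scr_ref: float = SCR_REF,
                     dfi_ref: float = DFI_REF) -> ModelSpec:
    """Final covariate model: WT, Scr, DFI (power) and diuretic use
    (indicator) on CL; WT (power) on V; proportional error; IIV on CL."""
    return ModelSpec(
        residual_model="proportional",
        iiv_parameters=("CL",),
        relations=(
            CovariateRelation("WT", "CL", "power", wt_ref),
            CovariateRelation("SCR", "CL", "power", scr_ref),
            CovariateRelation("DFI", "CL", "power", dfi_ref),
            CovariateRelation("DA", "CL", "exponential_indicator"),
            CovariateRelation("WT", "V", "power", wt_ref),
        ),
    )


def final_model_parameters() -> ParameterSet:
    """Reference estimates of the final NICU vancomycin model.

    tvCL 0.14 L/h, tvV 1.04 L; exponents 1.13 (WT on CL), -0.15 (Scr on
    CL), 0.14 (DFI on CL), 1.07 (WT on V); diuretic coefficient -0.20;
    IIV on CL 4.97 %CV; proportional residual 18.0 %CV.
    """
    return ParameterSet(
        theta={
            "tvCL": 0.14,
            "tvV": 1.04,
            "WT_on_CL": 1.13,
            "SCR_on_CL": -0.15,
            "DFI_on_CL": 0.14,
            "DA_on_CL": -0.20,
            "WT_on_V": 1.07,
        },
        omega={"CL": 0.0497 ** 2},
        sigma={"proportional": 0.18},
    )


def base_model_spec() -> ModelSpec:
    """Covariate-free base model: proportional error, IIV on CL and V."""
    return ModelSpec(residual_model="proportional", iiv_parameters=("CL", "V"), relations=())


def base_model_inits() -> ParameterSet:
    """Neutral starting values for the base model."""
    return ParameterSet(
        theta={"tvCL": 0.1, "tvV": 1.0},
        omega={"CL": 0.2 ** 2, "V": 0.2 ** 2},
        sigma={"proportional": 0.2},
    )
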