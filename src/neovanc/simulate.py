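"""Virtual NICU cohorts with the study's covariate structure and design.

Covariates are drawn from a Gaussian copula with log-normal margins
matched by (median, IQR) to the observed baseline distributions of the
modelled NICU population (e.g. weight median 1.98 kg, IQR 1.35-2.98;
serum creatinine median 32.48 umol/L; daily fluid input median 364 mL).
The two reported joint constraints are honoured on the latent scale:
corr(WT, PMA) = 0.8696 and corr(WT, DFI) = 0.7274; remaining cross-
correlations among the correlated block follow the conditional-
independence product (needed for positive definiteness) and all other
covariates are independent.  Binary covariates are Bernoulli draws at
the observed prevalences (diuretic use 33.3%).

The dosing design emulates clinical practice: 10-15 mg/kg per dose
(rounded to 0.5 mg), every 8 or 12 h, 1-h infusions.  Sampling is at
steady state: one trough 0.5 h before the 5th dose and one peak 0.5 h
after the end of the 5th infusion; a configurable fraction of subjects
(default 52%) contribute the trough only.  Simulated concentrations
outside the 2-50 mg/L assay calibration range are flagged excluded.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy import stats

from .model import (
    CALIBRATION_RANGE,
    Covariates,
    DoseEvent,
    ModelSpec,
    Observation,
    ParameterSet,
    Subject,
    ValidationError,
    individual_params,
    concentration,
    final_model_parameters,
    final_model_spec,
    within_calibration,
)

__all__ = [
    "CohortConfig",
    "TABLE_CONTINUOUS",
    "TABLE_BINARY",
    "generate_covariates",
    "generate_regimen",
    "simulate_dataset",
    "simulate_cohort",
    "split_cohort",
    "nearest_positive_definite",
]

_Z75 = stats.norm.ppf(0.75)

#: (median, q25, q75) targets for the continuous covariates.
TABLE_CONTINUOUS: dict[str, tuple[float, float, float]] = {
    "WT": (1.98, 1.35, 2.98),      # kg
    "PMA": (35.7, 32.9, 39.98),    # weeks
    "SCR": (32.48, 24.54, 42.31),  # umol/L
    "DFI": (364.0, 252.91, 473.1), # mL/day
    "DUV": (200.5, 156.75, 283.25),# mL/day
    "ALB": (28.5, 25.07, 31.55),   # g/L
    "ALT": (10.69, 6.46, 15.53),   # U/L
    "AST": (28.95, 21.38, 41.9),   # U/L
    "BUN": (3.57, 2.31, 5.86),     # mmol/L
}

#: Bernoulli prevalences for binary covariates.
TABLE_BINARY: dict[str, float] = {
    "DA": 0.333,
    "SEX": 0.683,   # male = 1
    "PM": 0.738,    # preterm
    "RS": 0.302,
    "PTZ": 0.095,
    "HA": 0.198,
    "VAA": 0.317,
}

#: Ordinal critical-illness score: 0 = non-critical (>90),
#: 1 = critical (70-90), 2 = extremely critical (<70).
NCIS_PROBS = (0.079, 0.699, 0.222)

#: Latent correlations honoured by the copula.
DEFAULT_CORRELATIONS: dict[tuple[str, str], float] = {
    ("WT", "PMA"): 0.8696,
    ("WT", "DFI"): 0.7274,
}


@dataclass
class CohortConfig:
    """Study-design knobs for a virtual cohort.

    Defaults are the conditions of the modelled NICU cohort; override
    only to scale experiments, not to change the emulated study.
    """

    n: int = 112
    continuous: dict = field(default_factory=lambda: dict(TABLE_CONTINUOUS))
    binary: dict = field(default_factory=lambda: dict(TABLE_BINARY))
    ncis_probs: tuple = NCIS_PROBS
    correlations: dict = field(default_factory=lambda: dict(DEFAULT_CORRELATIONS))
    dose_per_kg: tuple[float, float] = (10.0, 15.0)   # mg/kg per dose
    intervals: tuple[float, ...] = (8.0, 12.0)        # h
    infusion_duration: float = 1.0                    # h
    n_doses: int = 6
    sample_dose_index: int = 5      # 1-based; first dose after the 4-dose run-in
    trough_offset: float = 0.5      # h before next dose start
    peak_offset: float = 0.5        # h after infusion end
    trough_only_fraction: float = 0.52
    calibration: tuple[float, float] = CALIBRATION_RANGE

    def __post_init__(self) -> None:
        if self.n < 0:
            raise ValidationError("cohort size must be >= 0")
        if not 0.0 <= self.trough_only_fraction <= 1.0:
            raise ValidationError("trough_only_fraction must be in [0, 1]")
        for name, (med, lo, hi) in self.continuous.items():
            if not (lo < hi and med > 0 and lo > 0):
                raise ValidationError(f"bad (median, q25, q75) for {name}")
        if self.sample_dose_index > self.n_doses:
            raise ValidationError("sampling dose index beyond the dose history")


def nearest_positive_definite(corr: np.ndarray, floor: float = 1e-8) -> np.ndarray:
    """Eigenvalue-clipped repair of a correlation matrix."""
    evals, evecs = np.linalg.eigh(corr)
    if np.all(evals > floor):
        return corr
    evals = np.clip(evals, floor, None)
    fixed = (evecs * evals) @ evecs.T
    d = np.sqrt(np.diag(fixed))
    return fixed / np.outer(d, d)


def _lognormal_params(median: float, q25: float, q75: float) -> tuple[float, float]:
    mu = math.log(median)
    sd = math.log(q75 / q25) / (2.0 * _Z75)
    return mu, sd


def _latent_for_pearson(rho: float, s_a: float, s_b: float) -> float:
    """Latent (normal-scale) correlation giving Pearson ``rho`` between
    log-normal margins with log-SDs ``s_a``, ``s_b`` (exact inversion of
    the log-normal correlation formula)."""
    amp = math.sqrt(math.expm1(s_a ** 2) * math.expm1(s_b ** 2))
    r = math.log1p(rho * amp) / (s_a * s_b)
    return max(-1.0, min(1.0, r))


def _latent_correlation(config: CohortConfig, names: list[str]) -> np.ndarray:
    corr = np.eye(len(names))
    given = {}
    sds = {n: _lognormal_params(*config.continuous[n])[1] for n in names}
    for (a, b), rho in config.correlations.items():
        if a in names and b in names:
            ia, ib = names.index(a), names.index(b)
            r = _latent_for_pearson(rho, sds[a], sds[b])
            corr[ia, ib] = corr[ib, ia] = r
            given[(a, b)] = r
    # fill unspecified pairs within the correlated block by the
    # conditional-independence product through the shared hub (WT)
    hub = "WT"
    linked = sorted({x for pair in given for x in pair if x != hub})
    for i, a in enumerate(linked):
        for b in linked[i + 1:]:
            ra = given.get((hub, a), given.get((a, hub)))
            rb = given.get((hub, b), given.get((b, hub)))
            if ra is not None and rb is not None:
                ia, ib = names.index(a), names.index(b)
                if corr[ia, ib] == 0.0:
                    corr[ia, ib] = corr[ib, ia] = ra * rb
    return nearest_positive_definite(corr)


def generate_covariates(config: CohortConfig, seed: int | np.random.Generator = 0) -> list[Covariates]:
    """Draw a cohort of covariate vectors from the calibrated copula."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    if config.n == 0:
        return []
    names = list(config.continuous)
    corr = _latent_correlation(config, names)
    chol = np.linalg.cholesky(corr)
    z = rng.standard_normal(size=(config.n, len(names))) @ chol.T
    values = {}
    for j, name in enumerate(names):
        mu, sd = _lognormal_params(*config.continuous[name])
        values[name] = np.exp(mu + sd * z[:, j])
    for name, prev in config.binary.items():
        values[name] = (rng.random(config.n) < prev).astype(float)
    values["NCIS"] = rng.choice(len(config.ncis_probs), size=config.n,
                                p=config.ncis_probs).astype(float)
    out = []
    for i in range(config.n):
        out.append(Covariates(**{k: float(v[i]) for k, v in values.items()}))
    return out


def generate_regimen(cov: Mapping, config: CohortConfig | None = None,
                     seed: int | np.random.Generator = 0) -> list[DoseEvent]:
    """Steady-state dosing history for one subject.

    One per-kg dose level is drawn per subject (Uniform 10-15 mg/kg,
    rounded to 0.5 mg per dose), the interval is 8 h or 12 h with equal
    probability, infusions last 1 h, and at least five doses are given
    so sampling happens after the fourth.
    """
    config = config or CohortConfig()
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    wt = float(cov["WT"])
    if not wt > 0:
        raise ValidationError("WT must be > 0")
    lo, hi = config.dose_per_kg
    amount = round(wt * rng.uniform(lo, hi) * 2.0) / 2.0
    amount = max(amount, 0.5)
    interval = float(rng.choice(config.intervals))
    n_doses = max(config.n_doses, config.sample_dose_index)
    return [
        DoseEvent(start_time=i * interval, amount=amount,
                  duration=config.infusion_duration)
        for i in range(n_doses)
    ]


def simulate_dataset(cohort: Sequence[Mapping], regimens: Sequence[Sequence[DoseEvent]],
                     params: ParameterSet, spec: ModelSpec,
                     seed: int | np.random.Generator = 0,
                     config: CohortConfig | None = None) -> list[Subject]:
    """Simulate steady-state trough/peak observations for a cohort.

    Per subject: draw eta ~ N(0, Omega), evaluate the analytic model at
    the design times, apply the residual-error model, then flag
    observations outside the calibration range as excluded.  Subjects
    losing every observation to the filter are dropped (counted via the
    returned list length).
    """
    config = config or CohortConfig()
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    if len(cohort) != len(regimens):
        raise ValidationError("cohort and regimens must align")
    lo, hi = config.calibration
    subjects = []
    for i, (cov, doses) in enumerate(zip(cohort, regimens)):
        eta = {p: rng.normal(0.0, math.sqrt(max(params.omega.get(p, 0.0), 0.0)))
               for p in spec.iiv_parameters}
        cl, v = individual_params(params.theta, eta, cov, spec)
        ref = doses[config.sample_dose_index - 1]
        times_kinds = [(ref.start_time - config.trough_offset, "trough")]
        trough_only = rng.random() < config.trough_only_fraction
        if not trough_only:
            times_kinds.append((ref.end_time + config.peak_offset, "peak"))
        observations = []
        for t, kind in times_kinds:
            f = concentration(t, doses, cl, v)
            y = _apply_residual(f, params.sigma, spec.residual_model, rng)
            if y <= 0:
                continue  # unphysical draw; cannot be a valid assay record
            observations.append(Observation(
                time=t, concentration=y, kind=kind,
                excluded=not (lo <= y <= hi),
            ))
        if not any(not o.excluded for o in observations):
            continue
        subjects.append(Subject(
            id=f"S{i + 1:03d}", doses=tuple(doses),
            observations=tuple(observations), covariates=Covariates(**cov),
        ))
    return subjects


def _apply_residual(f: float, sigma: Mapping, residual_model: str,
                    rng: np.random.Generator) -> float:
    if residual_model == "additive":
        return f + rng.normal(0.0, sigma["additive"])
    if residual_model == "proportional":
        return f * (1.0 + rng.normal(0.0, sigma["proportional"]))
    if residual_model == "combined":
        return (f * (1.0 + rng.normal(0.0, sigma["proportional"]))
                + rng.normal(0.0, sigma["additive"]))
    raise ValidationError(f"unknown residual model {residual_model!r}")


def simulate_cohort(config: CohortConfig | None = None,
                    params: ParameterSet | None = None,
                    spec: ModelSpec | None = None,
                    seed: int = 0) -> list[Subject]:
    """Covariates + regimens + observations in one deterministic call."""
    config = config or CohortConfig()
    params = params or final_model_parameters()
    spec = spec or final_model_spec()
    rng = np.random.default_rng(seed)
    cohort = generate_covariates(config, rng)
    regimens = [generate_regimen(cov, config, rng) for cov in cohort]
    return simulate_dataset(cohort, regimens, params, spec, rng, config)


def split_cohort(subjects: Sequence[Subject], n_validation: int,
                 seed: int = 0) -> tuple[list[Subject], list[Subject]]:
    """Random modelling/validation split (the study used 112/14)."""
    if n_validation >= len(subjects):
        raise ValidationError("validation split larger than the cohort")
    rng = np.random.default_rng(seed)
    idx = rng.permutation(len(subjects))
    val = set(idx[:n_validation].tolist())
    modeling = [s for i, s in enumerate(subjects) if i not in val]
    validation = [s for i, s in enumerate(subjects) if i in val]
    return modeling, validation
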