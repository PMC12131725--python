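"""FOCE estimation of the nonlinear mixed-effects PK model.

The marginal -2 log-likelihood is approximated by first-order
conditional estimation with interaction (FOCE-I).  For each subject the
empirical-Bayes mode ``eta_hat`` minimises the conditional objective

    sum_j [ (y_j - f_j(eta))^2 / R_j(eta) + ln R_j(eta) ] + eta' Omega^-1 eta

with ``R`` the residual variance evaluated at the individual prediction
(the "interaction" part).  The model is then linearised about
``eta_hat``:  ``G_i = df_i/deta`` at the mode, ``Sigma_i = G_i Omega
G_i' + R_i(eta_hat)``, ``r_i = y_i - f_i(eta_hat) + G_i eta_hat``, and

    OFV = sum_i [ ln det Sigma_i + r_i' Sigma_i^-1 r_i + n_i ln 2*pi ].

The ``n ln 2*pi`` constant is retained; every model-building decision
rests on OFV differences, which the constant does not affect.

Implementation notes: eta optimisation is a damped Newton iteration
(finite-difference gradient/Hessian) vectorised across all subjects at
once, started from 0 with one fixed jittered restart; the outer search
runs L-BFGS-B on transformed parameters (log scale for tvCL, tvV,
omega and sigma; identity for covariate coefficients), with a
Nelder-Mead polish when the gradient-based step stalls.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import optimize

from .model import (
    ModelSpec,
    ParameterSet,
    Subject,
    ValidationError,
    residual_variance,
    typical_params,
)

__all__ = [
    "CompiledDataset",
    "FitResult",
    "ConvergenceError",
    "NumericalError",
    "estimate_etas",
    "foce_ofv",
    "fit_model",
    "compute_residuals",
    "standard_errors",
    "default_inits",
]

_LN2PI = math.log(2.0 * math.pi)
_ETA_FD_STEP = 1e-4
_INNER_GTOL = 1e-8
_R_FLOOR = 1e-12


class ConvergenceError(RuntimeError):
    pass


class NumericalError(RuntimeError):
    pass


# ---------------------------------------------------------------------------
# compiled dataset: padded dose arrays + flattened observations
# ---------------------------------------------------------------------------

class CompiledDataset:
    """Vectorised view of a list of subjects for a given model spec.

    Dose histories are padded to a rectangle; non-excluded observations
    are flattened and grouped contiguously by subject so per-subject
    reductions are ``bincount``/``reduceat`` calls.  Time-dependent
    pieces of the infusion superposition are precomputed once.
    """

    def __init__(self, subjects: Sequence[Subject], spec: ModelSpec):
        self.spec = spec
        usable: list[tuple[Subject, list]] = []
        self.n_excluded = 0
        self.n_dropped_subjects = 0
        for s in subjects:
            obs = [o for o in s.observations if not o.excluded]
            self.n_excluded += len(s.observations) - len(obs)
            if obs:
                usable.append((s, sorted(obs, key=lambda o: o.time)))
            else:
                self.n_dropped_subjects += 1
        if not usable:
            raise ValidationError("no subject with a usable observation")
        self.subjects = [s for s, _ in usable]
        n = self.n_subjects = len(usable)

        dmax = max(len(s.doses) for s in self.subjects)
        self.dose_start = np.zeros((n, dmax))
        self.dose_rate = np.zeros((n, dmax))
        self.dose_dur = np.ones((n, dmax))
        self.dose_mask = np.zeros((n, dmax), dtype=bool)
        for i, s in enumerate(self.subjects):
            for j, d in enumerate(s.doses):
                self.dose_start[i, j] = d.start_time
                self.dose_rate[i, j] = d.rate
                self.dose_dur[i, j] = d.duration
                self.dose_mask[i, j] = True

        # covariate columns shared by every subject
        keys = set(self.subjects[0].covariates)
        for s in self.subjects[1:]:
            keys &= set(s.covariates)
        self.covariates = {
            k: np.array([float(s.covariates[k]) for s in self.subjects]) for k in keys
        }

        obs_t, obs_y, obs_subj, obs_kind = [], [], [], []
        for i, (_, obs) in enumerate(usable):
            for o in obs:
                obs_t.append(o.time)
                obs_y.append(o.concentration)
                obs_subj.append(i)
                obs_kind.append(o.kind)
        self.obs_t = np.array(obs_t)
        self.obs_y = np.array(obs_y)
        self.obs_subj = np.array(obs_subj, dtype=np.intp)
        self.obs_kind = np.array(obs_kind)
        self.n_obs = len(obs_t)
        self.counts = np.bincount(self.obs_subj, minlength=n)
        self.offsets = np.concatenate([[0], np.cumsum(self.counts)])

        # parameter-independent pieces of the superposition
        o_start = self.dose_start[self.obs_subj]
        o_dur = self.dose_dur[self.obs_subj]
        dt = self.obs_t[:, None] - o_start
        self._te = np.clip(np.minimum(dt, o_dur), 0.0, None)
        self._after = np.clip(dt - o_dur, 0.0, None)
        self._active = self.dose_mask[self.obs_subj] & (dt > 0)
        self._o_rate = np.where(self._active, self.dose_rate[self.obs_subj], 0.0)

        # time after most recent dose start (for binning/plots)
        started = np.where(dt >= 0, o_start, -np.inf)
        last = np.max(np.where(self.dose_mask[self.obs_subj], started, -np.inf), axis=1)
        self.obs_tad = self.obs_t - np.where(np.isfinite(last), last, 0.0)

        iiv = spec.iiv_parameters
        self.k = len(iiv)
        self._i_cl = iiv.index("CL") if "CL" in iiv else None
        self._i_v = iiv.index("V") if "V" in iiv else None

    # -- model evaluation ---------------------------------------------------

    def typical(self, theta: Mapping):
        cl, v = typical_params(theta, self.covariates, self.spec)
        shape = (self.n_subjects,)
        return (np.broadcast_to(np.asarray(cl, dtype=float), shape),
                np.broadcast_to(np.asarray(v, dtype=float), shape))

    def predict(self, cl_pop: np.ndarray, v_pop: np.ndarray, eta: np.ndarray) -> np.ndarray:
        """Per-observation concentrations; ``eta`` has shape (..., n_subj, k)
        and the result broadcasts to (..., n_obs)."""
        cl = cl_pop
        v = v_pop
        if self._i_cl is not None:
            cl = cl_pop * np.exp(eta[..., self._i_cl])
        if self._i_v is not None:
            v = v_pop * np.exp(eta[..., self._i_v])
        cl_o = cl[..., self.obs_subj]
        ke = (cl / v)[..., self.obs_subj]
        term = (self._o_rate / cl_o[..., None]) \
            * (-np.expm1(-ke[..., None] * self._te)) \
            * np.exp(-ke[..., None] * self._after)
        return np.sum(term, axis=-1)

    def per_subject_sum(self, values: np.ndarray) -> np.ndarray:
        return np.bincount(self.obs_subj, weights=values, minlength=self.n_subjects)


# ---------------------------------------------------------------------------
# inner problem: empirical Bayes modes
# ---------------------------------------------------------------------------

def _omega_vector(params: ParameterSet, spec: ModelSpec) -> np.ndarray:
    return np.array([max(params.omega.get(p, 0.0), 0.0) for p in spec.iiv_parameters])


def _inner_modes(data: CompiledDataset, params: ParameterSet,
                 max_iter: int = 60) -> np.ndarray:
    """Empirical-Bayes eta modes for all subjects, vectorised Newton.

    The search runs on the standardised effects z = eta/omega (unit
    prior curvature, so conditioning stays O(1) even as omega -> 0):
    damped Newton from z = 0 with finite-difference derivatives plus one
    fixed jittered restart; the lower conditional objective wins.
    """
    n, k = data.n_subjects, data.k
    if k == 0:
        return np.zeros((n, 0))
    cl_pop, v_pop = data.typical(params.theta)
    omega = _omega_vector(params, data.spec)
    # dims with negligible variance (< 0.001% CV) are fully shrunk to zero
    free = omega > 1e-10
    sd = np.where(free, np.sqrt(np.maximum(omega, 1e-300)), 0.0)

    def obj(z):
        f = data.predict(cl_pop, v_pop, z * sd[None, :])
        r = np.maximum(residual_variance(f, params.sigma,
                                         data.spec.residual_model), _R_FLOOR)
        terms = (data.obs_y - f) ** 2 / r + np.log(r)
        return data.per_subject_sum(terms) + np.sum(z * z, axis=1)

    h = _ETA_FD_STEP

    def grad_hess(z):
        base = obj(z)
        g = np.zeros((n, k))
        hess = np.zeros((n, k, k))
        plus = []
        minus = []
        for d in range(k):
            zp = z.copy(); zp[:, d] += h
            zm = z.copy(); zm[:, d] -= h
            op, om = obj(zp), obj(zm)
            plus.append(op); minus.append(om)
            g[:, d] = (op - om) / (2 * h)
            hess[:, d, d] = (op - 2 * base + om) / h ** 2
        for d in range(k):
            for e in range(d + 1, k):
                zpp = z.copy(); zpp[:, d] += h; zpp[:, e] += h
                zmm = z.copy(); zmm[:, d] -= h; zmm[:, e] -= h
                cross = (obj(zpp) + obj(zmm) - plus[d] - minus[d]
                         - plus[e] - minus[e] + 2 * base) / (2 * h ** 2)
                hess[:, d, e] = hess[:, e, d] = cross
        return base, g, hess

    def newton(z0):
        z = z0.copy()
        z[:, ~free] = 0.0
        val = obj(z)
        for _ in range(max_iter):
            base, g, hess = grad_hess(z)
            g[:, ~free] = 0.0
            if np.max(np.abs(g)) < _INNER_GTOL * (1.0 + np.max(np.abs(base))):
                break
            # regularise per-subject Hessians to be PD
            eye = np.eye(k)
            evals = np.linalg.eigvalsh(hess)
            lam = np.clip(1e-6 - evals[:, 0], 0.0, None)
            hreg = hess + lam[:, None, None] * eye[None, :, :]
            hreg[:, ~free, :] = 0.0
            hreg[:, :, ~free] = 0.0
            hreg[:, ~free, ~free] = 1.0
            try:
                step = np.linalg.solve(hreg, g[..., None])[..., 0]
            except np.linalg.LinAlgError:
                step = g / np.maximum(np.abs(np.diagonal(hreg, axis1=1, axis2=2)), 1e-8)
            step[:, ~free] = 0.0
            step = np.clip(step, -20.0, 20.0)
            alpha = np.ones(n)
            for _ in range(25):
                trial = z - alpha[:, None] * step
                tval = obj(trial)
                worse = tval > base + 1e-12
                if not np.any(worse):
                    break
                alpha[worse] *= 0.5
            z = z - alpha[:, None] * step
            newval = obj(z)
            if np.max(np.abs(newval - val)) < 1e-13 * (1 + np.max(np.abs(val))):
                val = newval
                break
            val = newval
        return z, obj(z)

    z_a, val_a = newton(np.zeros((n, k)))
    jitter = np.full((n, k), 0.5)
    jitter[:, ~free] = 0.0
    z_b, val_b = newton(jitter)
    take_b = val_b < val_a - 1e-10
    eta = np.where(take_b[:, None], z_b, z_a) * sd[None, :]
    if not np.all(np.isfinite(eta)):
        bad = np.where(~np.all(np.isfinite(eta), axis=1))[0]
        raise ConvergenceError(
            f"non-finite eta mode for subject {data.subjects[bad[0]].id}"
        )
    return eta


def estimate_etas(subject: Subject, theta: Mapping, omega: Mapping, sigma: Mapping,
                  spec: ModelSpec) -> dict:
    """Empirical-Bayes eta mode for a single subject.

    Returns a mapping over ``spec.iiv_parameters``; parameters with zero
    omega are fully shrunk to zero.
    """
    params = ParameterSet(dict(theta), dict(omega), dict(sigma))
    data = CompiledDataset([subject], spec)
    eta = _inner_modes(data, params)[0]
    return {p: float(eta[i]) for i, p in enumerate(spec.iiv_parameters)}


# ---------------------------------------------------------------------------
# FOCE objective
# ---------------------------------------------------------------------------

def _foce_components(data: CompiledDataset, params: ParameterSet):
    """eta modes, predictions, linearisation and per-subject OFV pieces."""
    cl_pop, v_pop = data.typical(params.theta)
    eta = _inner_modes(data, params)
    n, k = data.n_subjects, data.k
    f_hat = data.predict(cl_pop, v_pop, eta)
    r_var = np.maximum(
        residual_variance(f_hat, params.sigma, data.spec.residual_model), _R_FLOOR
    )
    # G = df/deta at the mode, by central differences
    g_mat = np.zeros((data.n_obs, k))
    h = _ETA_FD_STEP
    for d in range(k):
        ep = eta.copy(); ep[:, d] += h
        em = eta.copy(); em[:, d] -= h
        g_mat[:, d] = (data.predict(cl_pop, v_pop, ep)
                       - data.predict(cl_pop, v_pop, em)) / (2 * h)
    omega = _omega_vector(params, data.spec)
    eta_obs = eta[data.obs_subj]
    resid = data.obs_y - f_hat + np.sum(g_mat * eta_obs, axis=1)

    ofv_i = np.zeros(n)
    chol_blocks: list[np.ndarray] = [None] * n
    for cnt in np.unique(data.counts):
        idx = np.where(data.counts == cnt)[0]
        rows = np.concatenate(
            [np.arange(data.offsets[i], data.offsets[i] + cnt) for i in idx]
        ).reshape(len(idx), cnt)
        gb = g_mat[rows]                      # (m, cnt, k)
        rb = resid[rows]                      # (m, cnt)
        vb = r_var[rows]
        sig = np.einsum("mik,k,mjk->mij", gb, omega, gb)
        sig[:, np.arange(cnt), np.arange(cnt)] += vb
        try:
            chol = np.linalg.cholesky(sig)
        except np.linalg.LinAlgError:
            for j, i in enumerate(idx):
                try:
                    np.linalg.cholesky(sig[j])
                except np.linalg.LinAlgError:
                    raise NumericalError(
                        f"singular observation covariance for subject {data.subjects[i].id}"
                    ) from None
            raise
        logdet = 2.0 * np.sum(np.log(np.diagonal(chol, axis1=1, axis2=2)), axis=1)
        sol = np.linalg.solve(sig, rb[..., None])[..., 0]
        quad = np.sum(rb * sol, axis=1)
        ofv_i[idx] = logdet + quad + cnt * _LN2PI
        for j, i in enumerate(idx):
            chol_blocks[i] = chol[j]
    return {
        "eta": eta,
        "f_hat": f_hat,
        "g": g_mat,
        "resid": resid,
        "r_var": r_var,
        "ofv_by_subject": ofv_i,
        "ofv": float(np.sum(ofv_i)),
        "chol": chol_blocks,
    }


def foce_ofv(data, params: ParameterSet, spec: ModelSpec | None = None) -> float:
    """FOCE-I objective function value (-2 log-likelihood approximation)."""
    if not isinstance(data, CompiledDataset):
        if spec is None:
            raise ValidationError("spec required when passing raw subjects")
        data = CompiledDataset(data, spec)
    return _foce_components(data, params)["ofv"]


# ---------------------------------------------------------------------------
# outer problem
# ---------------------------------------------------------------------------

class _Packer:
    """Maps ParameterSet <-> flat optimisation vector.

    Scale parameters (tvCL, tvV, omega SDs, sigma SDs) are log-
    transformed so positivity is structural; covariate coefficients stay
    on the natural scale.
    """

    _LOG_LO, _LOG_HI = -12.0, 6.0
    _LIN_LO, _LIN_HI = -20.0, 20.0

    def __init__(self, spec: ModelSpec):
        self.spec = spec
        self.entries: list[tuple[str, str, str]] = [
            ("theta", "tvCL", "log"), ("theta", "tvV", "log")
        ]
        for rel in spec.relations:
            self.entries.append(("theta", rel.name, "lin"))
        for p in spec.iiv_parameters:
            self.entries.append(("omega", p, "log"))
        for s in spec.sigma_names:
            self.entries.append(("sigma", s, "log"))
        self.n = len(self.entries)

    @property
    def names(self) -> list[str]:
        out = []
        for group, key, _ in self.entries:
            if group == "theta":
                out.append(key)
            elif group == "omega":
                out.append(f"omega_{key}")
            else:
                out.append(f"sigma_{key}")
        return out

    def pack(self, params: ParameterSet) -> np.ndarray:
        x = np.zeros(self.n)
        for i, (group, key, tr) in enumerate(self.entries):
            if group == "theta":
                v = params.theta[key]
            elif group == "omega":
                v = math.sqrt(max(params.omega.get(key, 1e-10), 1e-10))
            else:
                v = max(params.sigma.get(key, 1e-6), 1e-6)
            x[i] = math.log(v) if tr == "log" else v
        return x

    def unpack(self, x: np.ndarray) -> ParameterSet:
        params = ParameterSet(theta={}, omega={}, sigma={})
        for i, (group, key, tr) in enumerate(self.entries):
            v = math.exp(x[i]) if tr == "log" else float(x[i])
            if group == "theta":
                params.theta[key] = v
            elif group == "omega":
                params.omega[key] = v ** 2
            else:
                params.sigma[key] = v
        return params

    def natural(self, params: ParameterSet) -> np.ndarray:
        """Natural-scale vector (SDs for omega/sigma), for SE reporting."""
        x = np.zeros(self.n)
        for i, (group, key, _) in enumerate(self.entries):
            if group == "theta":
                x[i] = params.theta[key]
            elif group == "omega":
                x[i] = math.sqrt(max(params.omega.get(key, 0.0), 0.0))
            else:
                x[i] = params.sigma.get(key, 0.0)
        return x

    def from_natural(self, x: np.ndarray) -> ParameterSet:
        params = ParameterSet(theta={}, omega={}, sigma={})
        for i, (group, key, _) in enumerate(self.entries):
            if group == "theta":
                params.theta[key] = float(x[i])
            elif group == "omega":
                params.omega[key] = float(x[i]) ** 2
            else:
                params.sigma[key] = float(x[i])
        return params

    def bounds(self) -> list[tuple[float, float]]:
        return [
            (self._LOG_LO, self._LOG_HI) if tr == "log" else (self._LIN_LO, self._LIN_HI)
            for _, _, tr in self.entries
        ]


def default_inits(spec: ModelSpec) -> ParameterSet:
    """Neutral starting values: generic typical values, allometric prior
    for weight exponents, zero for other covariate coefficients."""
    theta = {"tvCL": 0.1, "tvV": 1.0}
    for rel in spec.relations:
        if rel.form == "power" and rel.covariate == "WT":
            theta[rel.name] = 0.75 if rel.parameter == "CL" else 1.0
        else:
            theta[rel.name] = 0.0
    omega = {p: 0.2 ** 2 for p in spec.iiv_parameters}
    sigma = {s: (0.2 if s == "proportional" else 1.0) for s in spec.sigma_names}
    return ParameterSet(theta, omega, sigma)


@dataclass
class FitResult:
    """Converged (or best-effort) FOCE fit."""

    estimates: ParameterSet
    spec: ModelSpec
    ofv: float
    converged: bool
    message: str
    n_subjects: int
    n_obs: int
    n_excluded: int
    etas: dict = field(default_factory=dict)        # subject id -> {param: eta}
    pred: np.ndarray | None = None
    ipred: np.ndarray | None = None
    cwres: np.ndarray | None = None
    rse_percent: dict | None = None
    se: dict | None = None
    n_function_evals: int = 0

    def residual_table(self, data: CompiledDataset | None = None) -> pd.DataFrame:
        if self._table is None:
            raise ValidationError("fit carries no residual table")
        return self._table.copy()

    _table: pd.DataFrame | None = None

    def to_dict(self) -> dict:
        return {
            "spec": self.spec.to_dict(),
            "estimates": self.estimates.to_dict(),
            "ofv": self.ofv,
            "converged": self.converged,
            "message": self.message,
            "n_subjects": self.n_subjects,
            "n_obs": self.n_obs,
            "n_excluded": self.n_excluded,
            "rse_percent": self.rse_percent,
            "se": self.se,
            "etas": self.etas,
        }

    def to_json(self, path=None, **kw) -> str:
        text = json.dumps(self.to_dict(), indent=2, **kw)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text

    @classmethod
    def from_dict(cls, d: Mapping) -> "FitResult":
        return cls(
            estimates=ParameterSet.from_dict(d["estimates"]),
            spec=ModelSpec.from_dict(d["spec"]),
            ofv=d["ofv"],
            converged=d["converged"],
            message=d.get("message", ""),
            n_subjects=d.get("n_subjects", 0),
            n_obs=d.get("n_obs", 0),
            n_excluded=d.get("n_excluded", 0),
            rse_percent=d.get("rse_percent"),
            se=d.get("se"),
            etas=d.get("etas", {}),
        )

    @classmethod
    def from_json(cls, path) -> "FitResult":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))


def fit_model(data, spec: ModelSpec, inits: ParameterSet | None = None,
              bounds=None, seed: int = 0, compute_se: bool = False,
              maxiter: int = 500, polish: bool = True) -> FitResult:
    """Maximum-likelihood (FOCE) fit of ``spec`` to ``data``.

    ``data`` may be a list of :class:`Subject` or a prebuilt
    :class:`CompiledDataset`.  The outer search is deterministic given
    ``seed`` (used only for the jittered restart taken when the primary
    start stalls).  Non-convergence returns the best iterate with
    ``converged=False`` rather than raising.
    """
    compiled = data if isinstance(data, CompiledDataset) else CompiledDataset(data, spec)
    packer = _Packer(spec)
    if inits is None:
        inits = default_inits(spec)
    inits.validate()
    x0 = packer.pack(inits)
    lob = packer.bounds() if bounds is None else bounds
    nev = [0]

    def objective(x):
        nev[0] += 1
        try:
            return _foce_components(compiled, packer.unpack(x))["ofv"]
        except (ConvergenceError, NumericalError, FloatingPointError):
            return 1e12

    with np.errstate(over="ignore", invalid="ignore", divide="ignore"):
        res = optimize.minimize(
            objective, x0, method="L-BFGS-B", bounds=lob,
            options={"maxiter": maxiter, "ftol": 1e-11, "gtol": 1e-7},
        )
        best_x, best_f, ok, msg = res.x, res.fun, res.success, str(res.message)
        if polish:
            pol = optimize.minimize(
                objective, best_x, method="Nelder-Mead",
                options={"maxiter": 150 * len(x0), "fatol": 1e-7, "xatol": 1e-7},
            )
            if pol.fun < best_f - 1e-9:
                best_x, best_f = pol.x, pol.fun
            ok = ok or pol.success
            # one L-BFGS-B pass from the polished point to confirm stationarity
            res2 = optimize.minimize(
                objective, best_x, method="L-BFGS-B", bounds=lob,
                options={"maxiter": maxiter, "ftol": 1e-11, "gtol": 1e-7},
            )
            if res2.fun <= best_f + 1e-9:
                best_x, best_f = res2.x, res2.fun
                ok = ok or res2.success
        if not ok:
            rng = np.random.default_rng(seed)
            x_j = x0 + rng.normal(scale=0.1, size=len(x0))
            res3 = optimize.minimize(
                objective, x_j, method="L-BFGS-B", bounds=lob,
                options={"maxiter": maxiter, "ftol": 1e-11, "gtol": 1e-7},
            )
            if res3.fun < best_f:
                best_x, best_f, ok, msg = res3.x, res3.fun, res3.success, str(res3.message)

    estimates = packer.unpack(best_x)
    comp = _foce_components(compiled, estimates)
    cl_pop, v_pop = compiled.typical(estimates.theta)
    pred = compiled.predict(cl_pop, v_pop, np.zeros_like(comp["eta"]))
    cwres = _cwres_from_components(compiled, comp)
    etas = {
        s.id: {p: float(comp["eta"][i, j]) for j, p in enumerate(spec.iiv_parameters)}
        for i, s in enumerate(compiled.subjects)
    }
    fit = FitResult(
        estimates=estimates, spec=spec, ofv=comp["ofv"], converged=bool(ok),
        message=msg, n_subjects=compiled.n_subjects, n_obs=compiled.n_obs,
        n_excluded=compiled.n_excluded, etas=etas, pred=pred,
        ipred=comp["f_hat"], cwres=cwres, n_function_evals=nev[0],
    )
    fit._table = _residual_frame(compiled, pred, comp["f_hat"], cwres)
    if compute_se:
        se, rse, approx = standard_errors(fit, compiled, spec)
        fit.se, fit.rse_percent = se, rse
        if approx:
            fit.message += " [SEs eigenvalue-adjusted]"
    return fit


def _cwres_from_components(data: CompiledDataset, comp) -> np.ndarray:
    from scipy.linalg import solve_triangular

    cwres = np.zeros(data.n_obs)
    for i in range(data.n_subjects):
        lo, hi = data.offsets[i], data.offsets[i + 1]
        chol = comp["chol"][i]
        cwres[lo:hi] = solve_triangular(chol, comp["resid"][lo:hi], lower=True)
    return cwres


def _residual_frame(data: CompiledDataset, pred, ipred, cwres) -> pd.DataFrame:
    ids = [data.subjects[i].id for i in data.obs_subj]
    return pd.DataFrame({
        "ID": ids,
        "TIME": data.obs_t,
        "TAD": data.obs_tad,
        "KIND": data.obs_kind,
        "DV": data.obs_y,
        "PRED": pred,
        "IPRED": ipred,
        "CWRES": cwres,
    })


def compute_residuals(fit: FitResult, data, spec: ModelSpec | None = None) -> pd.DataFrame:
    """PRED (eta=0), IPRED (eta at the mode) and CWRES per observation."""
    spec = spec or fit.spec
    compiled = data if isinstance(data, CompiledDataset) else CompiledDataset(data, spec)
    comp = _foce_components(compiled, fit.estimates)
    cl_pop, v_pop = compiled.typical(fit.estimates.theta)
    pred = compiled.predict(cl_pop, v_pop, np.zeros_like(comp["eta"]))
    cwres = _cwres_from_components(compiled, comp)
    return _residual_frame(compiled, pred, comp["f_hat"], cwres)


def standard_errors(fit: FitResult, data, spec: ModelSpec | None = None):
    """Asymptotic SEs from the central-difference Hessian of OFV/2.

    Works on the natural scale (SDs for omega/sigma).  A non-positive-
    definite Hessian is eigenvalue-adjusted and flagged approximate.
    Returns ``(se, rse_percent, approximate)`` dictionaries keyed like
    the packed parameter names.
    """
    spec = spec or fit.spec
    compiled = data if isinstance(data, CompiledDataset) else CompiledDataset(data, spec)
    packer = _Packer(spec)
    x = packer.natural(fit.estimates)
    m = len(x)

    def half_ofv(v):
        try:
            return 0.5 * _foce_components(compiled, packer.from_natural(v))["ofv"]
        except (ConvergenceError, NumericalError):
            return np.nan

    steps = np.maximum(np.abs(x) * 1e-3, 1e-5)
    hess = np.zeros((m, m))
    f0 = half_ofv(x)
    with np.errstate(all="ignore"):
        for i in range(m):
            for j in range(i, m):
                hi, hj = steps[i], steps[j]
                if i == j:
                    xp = x.copy(); xp[i] += hi
                    xm = x.copy(); xm[i] -= hi
                    hess[i, i] = (half_ofv(xp) - 2 * f0 + half_ofv(xm)) / hi ** 2
                else:
                    xpp = x.copy(); xpp[i] += hi; xpp[j] += hj
                    xpm = x.copy(); xpm[i] += hi; xpm[j] -= hj
                    xmp = x.copy(); xmp[i] -= hi; xmp[j] += hj
                    xmm = x.copy(); xmm[i] -= hi; xmm[j] -= hj
                    hess[i, j] = hess[j, i] = (
                        half_ofv(xpp) - half_ofv(xpm) - half_ofv(xmp) + half_ofv(xmm)
                    ) / (4 * hi * hj)
    approximate = False
    if not np.all(np.isfinite(hess)):
        hess = np.where(np.isfinite(hess), hess, 0.0)
        approximate = True
    evals, evecs = np.linalg.eigh(hess)
    if np.any(evals <= 0):
        approximate = True
        floor = max(1e-8, 1e-8 * np.max(np.abs(evals)))
        evals = np.clip(evals, floor, None)
        warnings.warn("non-positive-definite Hessian; SEs are eigenvalue-adjusted")
    cov = (evecs / evals) @ evecs.T
    se_vec = np.sqrt(np.clip(np.diag(cov), 0.0, None))
    names = packer.names
    se = {nm: float(s) for nm, s in zip(names, se_vec)}
    rse = {
        nm: float(100.0 * s / abs(v)) if abs(v) > 1e-12 else float("inf")
        for nm, s, v in zip(names, se_vec, x)
    }
    return se, rse, approximate
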