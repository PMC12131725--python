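"""Small independent oracles and toy model objects used across tests."""

from __future__ import annotations

import numpy as np
from scipy.integrate import solve_ivp

from neovanc.model import ModelSpec


class LinearEtaToy:
    """Duck-typed dataset whose prediction is linear in eta:
    f_ij = a_ij + b_ij * eta_i, with additive residual error.

    For this model the FOCE linearisation is exact, so the marginal
    -2 log-likelihood has the closed multivariate-normal form — an
    independent oracle for the estimation engine.
    """

    def __init__(self, a, b, y):
        counts = [len(ai) for ai in a]
        self.spec = ModelSpec(residual_model="additive", iiv_parameters=("CL",))
        self.k = 1
        self.a = np.concatenate(a)
        self.b = np.concatenate(b)
        self.obs_y = np.concatenate(y)
        self.n_obs = len(self.obs_y)
        self.n_subjects = len(counts)
        self.counts = np.array(counts)
        self.offsets = np.concatenate([[0], np.cumsum(counts)])
        self.obs_subj = np.repeat(np.arange(self.n_subjects), counts)

        class _S:
            def __init__(self, i):
                self.id = f"toy{i}"

        self.subjects = [_S(i) for i in range(self.n_subjects)]

    def typical(self, theta):
        ones = np.ones(self.n_subjects)
        return ones, ones

    def predict(self, cl_pop, v_pop, eta):
        return self.a + self.b * eta[..., self.obs_subj, 0]

    def per_subject_sum(self, values):
        return np.bincount(self.obs_subj, weights=values, minlength=self.n_subjects)

    def exact_m2ll(self, omega_var, sigma_sd):
        """Closed-form marginal -2 log-likelihood."""
        total = 0.0
        for i in range(self.n_subjects):
            lo, hi = self.offsets[i], self.offsets[i + 1]
            bi = self.b[lo:hi]
            r = self.obs_y[lo:hi] - self.a[lo:hi]
            cov = omega_var * np.outer(bi, bi) + sigma_sd ** 2 * np.eye(hi - lo)
            _, logdet = np.linalg.slogdet(cov)
            total += logdet + r @ np.linalg.solve(cov, r) + (hi - lo) * np.log(2 * np.pi)
        return total


def ode_concentration(times, doses, CL, V):
    """Numerical one-compartment infusion profile: piecewise integration
    of dC/dt = rate_in(t)/V - (CL/V) C between forcing breakpoints."""
    ke = CL / V
    times = np.asarray(times, dtype=float)
    bps = sorted(
        {0.0}
        | {d.start_time for d in doses}
        | {d.end_time for d in doses}
        | set(times.tolist())
    )
    c = 0.0
    value_at = {0.0: 0.0}
    for a, b in zip(bps[:-1], bps[1:]):
        rate = sum(d.rate for d in doses if d.start_time <= a and b <= d.end_time)
        sol = solve_ivp(
            lambda t, y: rate / V - ke * y[0], (a, b), [c],
            rtol=1e-11, atol=1e-13,
        )
        c = float(sol.y[0, -1])
        value_at[b] = c
    return np.array([value_at[t] for t in times])


def gauss_hermite_m2ll(subjects, theta, omega_sd, sigma_sd, spec, n_nodes=64):
    """Adaptive Gauss-Hermite marginal -2 log-likelihood for a one-eta
    (CL) model with additive error — the quadrature oracle."""
    from scipy.optimize import minimize_scalar

    from neovanc.model import concentration

    nodes, weights = np.polynomial.hermite.hermgauss(n_nodes)
    total = 0.0
    for s in subjects:
        y = np.array([o.concentration for o in s.active_observations])
        t = np.array([o.time for o in s.active_observations])

        def joint(eta):
            from neovanc.model import typical_params
            cl, v = typical_params(theta, s.covariates, spec)
            f = concentration(t, s.doses, cl * np.exp(eta), v)
            return np.sum((y - f) ** 2) / sigma_sd ** 2 + eta ** 2 / omega_sd ** 2

        mode = minimize_scalar(joint, bounds=(-4, 4), method="bounded",
                               options={"xatol": 1e-12}).x
        h = 1e-4
        curv = (joint(mode + h) - 2 * joint(mode) + joint(mode - h)) / h ** 2 / 2.0
        scale = 1.0 / np.sqrt(max(curv, 1e-12))

        def integrand(eta):
            return np.exp(-0.5 * joint(eta))

        vals = np.array([integrand(mode + np.sqrt(2) * scale * x) for x in nodes])
        integral = np.sqrt(2) * scale * np.sum(weights * vals * np.exp(nodes ** 2))
        n_i = len(y)
        const = (2 * np.pi * sigma_sd ** 2) ** (-n_i / 2) / np.sqrt(2 * np.pi * omega_sd ** 2)
        total += -2.0 * np.log(const * integral)
    return total
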