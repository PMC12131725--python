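"""Estimation engine: eta modes, FOCE objective, fitting, residuals, SEs."""

import math

import numpy as np
import pytest

from neovanc.estimation import (
    CompiledDataset,
    _foce_components,
    _inner_modes,
    estimate_etas,
    fit_model,
    foce_ofv,
    standard_errors,
)
from neovanc.model import (
    Covariates,
    DoseEvent,
    ModelSpec,
    Observation,
    ParameterSet,
    Subject,
    concentration,
    individual_params,
)
from neovanc.simulate import CohortConfig, simulate_cohort

from toys import LinearEtaToy, gauss_hermite_m2ll


def _exact_subject(spec, params, covariates, doses, times):
    """Subject whose observations equal the typical prediction exactly."""
    cl, v = individual_params(params.theta, {}, covariates, spec)
    obs = tuple(Observation(t, concentration(t, doses, cl, v)) for t in times)
    return Subject("exact", tuple(doses), obs, Covariates(**covariates))


COV = {"WT": 2.0, "SCR": 30.0, "DFI": 350.0, "DA": 0}
DOSES = [DoseEvent(12.0 * i, 26.0, 1.0) for i in range(5)]
TIMES = (47.5, 50.5)


class TestEtaModes:
    def test_zero_residuals_give_near_zero_mode(self, final_spec, final_params):
        s = _exact_subject(final_spec, final_params, COV, DOSES, TIMES)
        eta = estimate_etas(s, final_params.theta, final_params.omega,
                            final_params.sigma, final_spec)
        # proportional-error interaction shifts the mode slightly off zero
        assert abs(eta["CL"]) < 0.01

    def test_zero_residuals_additive_error_mode_is_zero(self, final_params):
        spec = ModelSpec(residual_model="additive", iiv_parameters=("CL",),
                         relations=())
        params = ParameterSet({"tvCL": 0.14, "tvV": 1.04}, {"CL": 0.05 ** 2},
                              {"additive": 1.0})
        s = _exact_subject(spec, params, COV, DOSES, TIMES)
        eta = estimate_etas(s, params.theta, params.omega, params.sigma, spec)
        assert abs(eta["CL"]) < 1e-6

    def test_vanishing_omega_fully_shrinks(self, final_spec, final_params):
        s = _exact_subject(final_spec, final_params, COV, DOSES, (47.5,))
        # perturb the observation so the unshrunk mode would be nonzero
        o = s.observations[0]
        s = Subject(s.id, s.doses,
                    (Observation(o.time, o.concentration * 1.4),), s.covariates)
        eta = estimate_etas(s, final_params.theta, {"CL": 0.0},
                            final_params.sigma, final_spec)
        assert eta["CL"] == 0.0

    def test_linear_one_observation_matches_ridge_solution(self):
        rng = np.random.default_rng(21)
        a, b, y = [rng.uniform(5, 15, 1)], [rng.uniform(0.5, 2, 1)], None
        om2, sig = 0.3, 0.8
        y = [a[0] + b[0] * rng.normal(0, np.sqrt(om2)) + rng.normal(0, sig, 1)]
        toy = LinearEtaToy(a, b, y)
        params = ParameterSet({"tvCL": 1.0, "tvV": 1.0}, {"CL": om2}, {"additive": sig})
        eta = _inner_modes(toy, params)[0, 0]
        closed = (b[0][0] * (y[0][0] - a[0][0]) / sig ** 2) / \
            (b[0][0] ** 2 / sig ** 2 + 1.0 / om2)
        assert eta == pytest.approx(closed, abs=1e-8)


class TestFoceObjective:
    def test_equals_iid_loglik_when_omega_zero(self, final_params):
        spec = ModelSpec(residual_model="additive", iiv_parameters=("CL",))
        subs = simulate_cohort(CohortConfig(n=10), seed=7)
        data = CompiledDataset(subs, spec)
        sig = 1.5
        params = ParameterSet({"tvCL": 0.14, "tvV": 1.04}, {"CL": 0.0},
                              {"additive": sig})
        ofv = foce_ofv(data, params)
        cl, v = data.typical(params.theta)
        resid = data.obs_y - data.predict(cl, v, np.zeros((data.n_subjects, 1)))
        exact = np.sum(np.log(sig ** 2) + resid ** 2 / sig ** 2 + np.log(2 * np.pi))
        assert ofv == pytest.approx(exact, abs=1e-8)

    def test_exact_for_linear_in_eta_model(self):
        rng = np.random.default_rng(42)
        counts = [2, 3, 1, 4]
        a = [rng.uniform(5, 15, c) for c in counts]
        b = [rng.uniform(-2, 2, c) for c in counts]
        om2, sig = 0.3, 0.8
        y = [ai + bi * rng.normal(0, np.sqrt(om2)) + rng.normal(0, sig, len(ai))
             for ai, bi in zip(a, b)]
        toy = LinearEtaToy(a, b, y)
        params = ParameterSet({"tvCL": 1.0, "tvV": 1.0}, {"CL": om2}, {"additive": sig})
        ofv = _foce_components(toy, params)["ofv"]
        assert ofv == pytest.approx(toy.exact_m2ll(om2, sig), abs=1e-8)

    def test_agrees_with_gauss_hermite_on_nonlinear_toy(self, final_spec):
        spec = ModelSpec(residual_model="additive", iiv_parameters=("CL",))
        rng = np.random.default_rng(3)
        theta = {"tvCL": 0.14, "tvV": 1.04}
        om, sig = 0.2, 1.0
        subs = []
        for i in range(2):
            doses = (DoseEvent(0, 25, 1), DoseEvent(12, 25, 1), DoseEvent(24, 25, 1))
            cl = 0.14 * np.exp(rng.normal(0, om))
            obs = []
            for t in (25.5, 35.5):
                f = concentration(t, doses, cl, 1.04)
                obs.append(Observation(t, max(f + rng.normal(0, sig), 0.01)))
            subs.append(Subject(f"Q{i}", doses, tuple(obs),
                                Covariates(WT=2.0, SCR=30.0, DFI=300.0, DA=0)))
        params = ParameterSet(theta, {"CL": om ** 2}, {"additive": sig})
        ofv = foce_ofv(subs, params, spec)
        exact = gauss_hermite_m2ll(subs, theta, om, sig, spec)
        assert abs(ofv - exact) < 0.1

    def test_invariant_to_subject_order(self, cohort60, final_spec, final_params):
        fwd = foce_ofv(cohort60, final_params, final_spec)
        rev = foce_ofv(list(reversed(cohort60)), final_params, final_spec)
        assert fwd == pytest.approx(rev, abs=1e-8)

    def test_invariant_to_consistent_time_rescaling(self, cohort60, final_spec, final_params):
        # minutes instead of hours with CL rescaled leaves concentrations,
        # hence the likelihood of a proportional-error model, unchanged
        scaled = []
        for s in cohort60:
            doses = tuple(DoseEvent(d.start_time * 60, d.amount, d.duration * 60)
                          for d in s.doses)
            obs = tuple(Observation(o.time * 60, o.concentration, o.kind, o.excluded)
                        for o in s.observations)
            scaled.append(Subject(s.id, doses, obs, s.covariates))
        params = final_params.copy()
        params.theta = dict(params.theta, tvCL=params.theta["tvCL"] / 60)
        base = foce_ofv(cohort60, final_params, final_spec)
        resc = foce_ofv(scaled, params, final_spec)
        assert resc == pytest.approx(base, rel=1e-8)


class TestFitModel:
    def test_refit_from_solution_is_fixed_point(self, data60, final_spec, fit60):
        refit = fit_model(data60, final_spec, inits=fit60.estimates, seed=5)
        assert refit.ofv == pytest.approx(fit60.ofv, abs=1e-6)

    def test_final_model_beats_base_on_covariate_data(self, cohort60):
        from neovanc.model import base_model_spec, final_model_spec
        base = fit_model(cohort60, base_model_spec(), seed=1)
        final = fit_model(cohort60, final_model_spec(), seed=1)
        assert final.ofv < base.ofv

    def test_recovers_generating_parameters_roughly(self, fit60, final_params):
        est = fit60.estimates
        assert est.theta["tvCL"] == pytest.approx(0.14, rel=0.15)
        assert est.theta["WT_on_CL"] == pytest.approx(1.13, abs=0.35)
        # sigma/omega split is weakly identified at ~1.5 obs/subject and
        # n = 60; their total variability is the well-determined quantity
        total = math.sqrt(est.sigma["proportional"] ** 2 + est.omega["CL"])
        truth = math.sqrt(0.18 ** 2 + 0.0497 ** 2)
        assert total == pytest.approx(truth, rel=0.25)


class TestResiduals:
    def test_cwres_reduces_to_standardised_residual_without_iiv(self, final_params):
        spec = ModelSpec(residual_model="additive", iiv_parameters=("CL",))
        subs = simulate_cohort(CohortConfig(n=8), seed=13)
        data = CompiledDataset(subs, spec)
        sig = 1.2
        params = ParameterSet({"tvCL": 0.14, "tvV": 1.04}, {"CL": 0.0}, {"additive": sig})
        comp = _foce_components(data, params)
        cl, v = data.typical(params.theta)
        f = data.predict(cl, v, np.zeros((data.n_subjects, 1)))
        from neovanc.estimation import _cwres_from_components
        cwres = _cwres_from_components(data, comp)
        np.testing.assert_allclose(cwres, (data.obs_y - f) / sig, rtol=1e-8)

    def test_ipred_equals_pred_at_zero_eta(self, data60, final_params):
        params = final_params.copy()
        params.omega = {"CL": 0.0}
        comp = _foce_components(data60, params)
        cl, v = data60.typical(params.theta)
        pred = data60.predict(cl, v, np.zeros_like(comp["eta"]))
        np.testing.assert_allclose(comp["f_hat"], pred, rtol=1e-10)

    def test_cwres_calibrated_under_generating_model(self, final_spec, final_params):
        subs = simulate_cohort(CohortConfig(n=150), final_params, final_spec, seed=31)
        data = CompiledDataset(subs, final_spec)
        assert data.n_obs >= 200
        comp = _foce_components(data, final_params)
        from neovanc.estimation import _cwres_from_components
        cwres = _cwres_from_components(data, comp)
        assert abs(cwres.mean()) < 0.15
        assert 0.7 < cwres.var(ddof=1) < 1.3


class TestStandardErrors:
    def test_sigma_se_matches_normal_theory(self):
        # additive error, no IIV: SE(sigma) ~ sigma / sqrt(2 n)
        spec = ModelSpec(residual_model="additive", iiv_parameters=())
        params = ParameterSet({"tvCL": 0.14, "tvV": 1.04}, {}, {"additive": 1.0})
        subs = simulate_cohort(CohortConfig(n=70, trough_only_fraction=0.0),
                               params, spec, seed=17)
        fit = fit_model(subs, spec, seed=17, compute_se=True)
        n = fit.n_obs
        sig = fit.estimates.sigma["additive"]
        assert fit.se["sigma_additive"] == pytest.approx(sig / math.sqrt(2 * n), rel=0.2)

    def test_rse_ordering_matches_information_content(self, fit60, data60, final_spec):
        _, rse, _ = standard_errors(fit60, data60, final_spec)
        # typical clearance is far better determined than the Scr exponent
        assert rse["tvCL"] < rse["SCR_on_CL"]
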