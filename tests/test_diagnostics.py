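"""Bootstrap, VPC, NPDE and external-validation diagnostics."""

import numpy as np
import pytest
from scipy.special import ndtri
from scipy.stats import spearmanr

from neovanc.diagnostics import (
    bootstrap,
    ebe_table,
    gof_tables,
    npde,
    prediction_errors,
    vpc,
)
from neovanc.estimation import CompiledDataset
from neovanc.model import (
    Covariates,
    DoseEvent,
    Observation,
    ParameterSet,
    Subject,
    concentration,
    individual_params,
)
from neovanc.simulate import CohortConfig, simulate_cohort


class TestBootstrap:
    def test_cloned_subjects_give_degenerate_intervals(self, cohort60, final_spec, fit60):
        template = max(cohort60, key=lambda s: len(s.active_observations))
        clones = [Subject(f"C{i}", template.doses, template.observations,
                          template.covariates) for i in range(15)]
        res = bootstrap(clones, final_spec, inits=fit60.estimates, n_boot=5, seed=4)
        for name in ("tvCL", "tvV"):
            width = res.ci_upper[name] - res.ci_lower[name]
            assert width <= 0.02 * abs(res.median[name])

    def test_medians_bracket_generating_values(self, final_spec, final_params):
        subs = simulate_cohort(CohortConfig(n=40), final_params, final_spec, seed=23)
        res = bootstrap(subs, final_spec, inits=final_params, n_boot=12, seed=23)
        assert res.n_success >= 10
        assert res.median["tvCL"] == pytest.approx(0.14, rel=0.10)
        assert res.median["tvV"] == pytest.approx(1.04, rel=0.10)
        assert res.ci_lower["tvCL"] <= res.median["tvCL"] <= res.ci_upper["tvCL"]


class TestVpc:
    def test_self_simulated_data_fall_inside_bands(self, data60, fit60):
        res = vpc(data60, fit60, n_sim=400, seed=6)
        assert res.coverage() >= 0.9

    def test_percentile_ordering_in_every_bin(self, data60, fit60):
        res = vpc(data60, fit60, n_sim=200, seed=7)
        for _, grp in res.table.groupby("bin"):
            by_pct = grp.sort_values("percentile")["observed"].to_numpy()
            assert np.all(np.diff(by_pct) >= 0)

    def test_gross_misspecification_is_detected(self, cohort60, final_spec, fit60):
        shifted = []
        for s in cohort60:
            obs = tuple(Observation(o.time, o.concentration * 10.0, o.kind,
                                    o.excluded)
                        for o in s.observations)
            shifted.append(Subject(s.id, s.doses, obs, s.covariates))
        res = vpc(CompiledDataset(shifted, final_spec), fit60, n_sim=300, seed=8)
        med = res.table[res.table.percentile == 50.0]
        outside = (med.observed > med.sim_ci_upper) | (med.observed < med.sim_ci_lower)
        assert outside.mean() > 0.5


class TestNpde:
    def test_calibrated_under_generating_model(self, final_spec, final_params):
        # large enough that the +/-0.1 mean band is a three-sigma check
        subs = simulate_cohort(CohortConfig(n=600), final_params, final_spec, seed=41)
        data = CompiledDataset(subs, final_spec)
        assert data.n_obs >= 800
        res = npde(data, final_params, n_sim=1000, seed=42, spec=final_spec)
        assert abs(res.mean) <= 0.1
        assert 0.85 <= res.variance <= 1.15
        assert res.p_global >= 0.0 and res.p_global <= 1.0

    def test_observation_below_all_simulations_gets_half_count(self, final_spec, final_params):
        doses = (DoseEvent(12.0 * i, 26.0, 1.0) for i in range(5))
        cov = Covariates(WT=2.0, SCR=30.0, DFI=350.0, DA=0)
        s = Subject("low", tuple(doses), (Observation(47.5, 2.0),), cov)
        n_sim = 500
        res = npde([s], final_params, n_sim=n_sim, seed=1, spec=final_spec)
        assert np.isfinite(res.npde[0])
        assert res.npde[0] == pytest.approx(ndtri(1.0 / (2 * n_sim)))

    def test_global_p_is_bonferroni_of_minimum(self, data60, final_params, final_spec):
        res = npde(data60, final_params, n_sim=300, seed=3, spec=final_spec)
        expected = min(1.0, 3.0 * min(res.p_ttest, res.p_variance, res.p_normality))
        assert res.p_global == pytest.approx(expected)


def _subject_with_obs(doses, times, concs):
    cov = Covariates(WT=2.12, SCR=30.52, DFI=367.18, DA=0)
    obs = tuple(Observation(t, c) for t, c in zip(times, concs))
    return Subject("V1", tuple(doses), obs, cov)


class TestPredictionErrors:
    def test_perfect_predictions_give_zero_errors(self, final_spec, final_params):
        doses = [DoseEvent(12.0 * i, 26.0, 1.0) for i in range(5)]
        cl, v = individual_params(final_params.theta, {},
                                 {"WT": 2.12, "SCR": 30.52, "DFI": 367.18, "DA": 0},
                                 final_spec)
        times = (47.5, 49.5)
        concs = [concentration(t, doses, cl, v) for t in times]
        rep = prediction_errors(final_params, final_spec,
                                [_subject_with_obs(doses, times, concs)])
        assert rep.mpe_percent == pytest.approx(0.0, abs=1e-10)
        assert rep.mape_percent == pytest.approx(0.0, abs=1e-10)
        assert rep.f20_percent == 100.0 and rep.f30_percent == 100.0

    def test_symmetric_twenty_percent_errors_inclusive_boundary(self, final_spec, final_params):
        doses = [DoseEvent(12.0 * i, 26.0, 1.0) for i in range(5)]
        cl, v = individual_params(final_params.theta, {},
                                 {"WT": 2.12, "SCR": 30.52, "DFI": 367.18, "DA": 0},
                                 final_spec)
        times = (47.5, 49.5)
        preds = [concentration(t, doses, cl, v) for t in times]
        concs = [preds[0] / 1.2, preds[1] / 0.8]   # PE exactly +20% and -20%
        rep = prediction_errors(final_params, final_spec,
                                [_subject_with_obs(doses, times, concs)])
        assert rep.mpe_percent == pytest.approx(0.0, abs=1e-9)
        assert rep.mape_percent == pytest.approx(20.0, rel=1e-9)
        assert rep.f20_percent == 100.0

    def test_scale_consistency(self, cohort60, final_spec, final_params):
        rep0 = prediction_errors(final_params, final_spec, cohort60)
        scale = 3.0
        scaled = []
        for s in cohort60:
            doses = tuple(DoseEvent(d.start_time, d.amount * scale, d.duration)
                          for d in s.doses)
            obs = tuple(Observation(o.time, o.concentration * scale, o.kind,
                                    o.excluded)
                        for o in s.observations)
            scaled.append(Subject(s.id, doses, obs, s.covariates))
        rep1 = prediction_errors(final_params, final_spec, scaled)
        assert rep1.mpe_percent == pytest.approx(rep0.mpe_percent, rel=1e-9)
        assert rep1.mape_percent == pytest.approx(rep0.mape_percent, rel=1e-9)
        assert rep1.f20_percent == rep0.f20_percent
        assert rep1.f30_percent == rep0.f30_percent

    def test_report_invariants(self, cohort60, final_spec, final_params):
        rep = prediction_errors(final_params, final_spec, cohort60)
        assert 0 <= rep.f20_percent <= rep.f30_percent <= 100
        assert rep.mape_percent >= abs(rep.mpe_percent)


class TestGof:
    def test_row_count_matches_active_observations(self, fit60, cohort60):
        table = gof_tables(fit60)
        n_active = sum(len(s.active_observations) for s in cohort60)
        assert len(table) == n_active
        assert {"DV", "PRED", "IPRED", "CWRES", "TAD"} <= set(table.columns)

    def test_ebe_clearance_declines_with_creatinine(self, fit60, cohort60):
        ebes = ebe_table(fit60, cohort60)
        rho, _ = spearmanr(ebes["SCR"], ebes["CL"])
        assert rho < 0


class TestPlots:
    def test_figures_written_to_disk(self, tmp_path, fit60, data60, cohort60,
                                     final_params, final_spec):
        from neovanc.plots import plot_cl_covariates, plot_gof, plot_npde, plot_vpc

        table = gof_tables(fit60)
        plot_gof(table, tmp_path / "gof.png")
        v = vpc(data60, fit60, n_sim=100, seed=9)
        plot_vpc(v.table, table, tmp_path / "vpc.png")
        res = npde(data60, final_params, n_sim=200, seed=9, spec=final_spec)
        plot_npde(res.npde, res.table, tmp_path / "npde.png")
        plot_cl_covariates(ebe_table(fit60, cohort60), tmp_path / "cl_cov.png")
        for name in ("gof.png", "vpc.png", "npde.png", "cl_cov.png"):
            assert (tmp_path / name).stat().st_size > 5000
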