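# Methods

## Structural and stochastic model

Disposition is a one-compartment model with zero-order infusion input
and first-order elimination.  For a dose infused at rate R0 starting at
t0 for duration D, the concentration contribution is
(R0/CL)(1 − e^(−k_e·Δt)) during the infusion and that value at the end
of infusion decayed by e^(−k_e·(t − t0 − D)) afterwards, with
k_e = CL/V.  Kinetics are linear, so arbitrary regimens are evaluated
by exact superposition over the full dose history; steady state is a
property of the simulated design (sampling after the fourth dose),
never a flag or approximation.  Times are hours since each subject's
first dose, amounts mg, concentrations mg/L.

Inter-individual variability is log-normal, P_i = P_TV·exp(η_i), η ~
N(0, ω²), diagonal Ω.  The final model carries IIV on CL only; the
covariate-free base model carries IIV on CL and V.  Residual error
models: additive, proportional and combined, on the observation scale
Y = F(1+ε1) + ε2.

Covariates enter multiplicatively: continuous ones as centred power
terms (x/x_ref)^θ, binary ones as exponential indicators exp(θ·I).
Centering constants default to the published reference values
(WT 2.12 kg, Scr 30.52 µmol/L, DFI 367.18 mL/day) when using the
shipped final model, and to dataset medians when screening new data;
they are always recorded in the `ModelSpec`, never silently recomputed.
IIV magnitude is reported as %CV = 100·ω by default; the log-normal
convention 100·sqrt(exp(ω²)−1) is available and differs only in the
fourth decimal at ω ≈ 0.05.

## Estimation (FOCE-I)

The inner problem finds each subject's empirical-Bayes mode η̂
minimising Σ_j[(y_j−f_j(η))²/R_j(η) + ln R_j(η)] + ηᵀΩ⁻¹η, with the
residual variance R evaluated at the individual prediction
(interaction).  It is solved on the standardised scale z = η/ω (unit
prior curvature, so conditioning is independent of ω) by a damped
Newton iteration with finite-difference derivatives (step 1e−4,
gradient tolerance 1e−8), vectorised across all subjects, started from
z = 0 with one fixed jittered restart; the lower conditional objective
wins, so the result is deterministic.  Dimensions with ω below 0.001 %CV
are treated as fully shrunk (η = 0).

The objective linearises the model about η̂: with G_i = ∂f_i/∂η at the
mode, Σ_i = G_i Ω G_iᵀ + R_i(η̂) and r_i = y_i − f_i(η̂) + G_i η̂,

    OFV = Σ_i [ ln det Σ_i + r_iᵀ Σ_i⁻¹ r_i + n_i ln 2π ].

The n ln 2π constant is retained; all model-building decisions rest on
OFV differences, which it cannot affect.  The linearisation is exact in
the Ω→0 and linear-in-η limits (asserted against closed forms in the
tests) and agrees with 64-node adaptive Gauss–Hermite quadrature within
0.1 OFV units on small nonlinear problems.

The outer search maximises the likelihood over transformed parameters
(log scale for tvCL, tvV and the ω/σ standard deviations; natural scale
for covariate coefficients) with L-BFGS-B (relative OFV tolerance
~1e−9), followed by a bounded Nelder–Mead polish and a confirming
gradient pass; a seeded jittered restart is taken if the primary start
stalls.  Screening and bootstrap refits skip the polish: their
decisions operate in chi-square units, orders of magnitude above the
polish's refinements.  Non-convergence returns the best iterate,
flagged.  Standard errors come from the central-difference Hessian of
OFV/2 on the natural scale; a non-positive-definite Hessian is
eigenvalue-adjusted and flagged approximate.

Observations outside the 2–50 mg/L calibration range are excluded
before fitting (with counts retained); no censored-data likelihood is
used, mirroring the study's exclusion criterion.  Default starting
values are deliberately neutral: tvCL 0.1 L/h, tvV 1 L, allometric
priors (0.75/1.0) for weight exponents, zero for other coefficients,
20 %CV for ω and σ.

## Covariate selection

Each candidate is one relation (the 3-level critical-illness score is a
group of two indicators counted as one step).  Forward addition accepts
the candidate with the largest OFV drop while the drop exceeds 3.84
(χ², p < 0.05, df 1); backward elimination removes the relation whose
removal raises OFV the least while the rise stays below 7.88
(p < 0.005).  Ties break lexicographically by (parameter, covariate);
a removed relation is not re-tested; the procedure is capped at 50
steps.  Candidate fits warm-start from the incumbent optimum; the final
model is verified by a cold-start refit.  The full decision trail (every
candidate tested at every step, with its ΔOFV and decision) is exported
as a table.

## Diagnostics

*Bootstrap* resamples subjects with replacement to the original count
and refits; non-convergent replicates are dropped and counted (> 20%
failures flags the result unreliable); medians and 2.5–97.5 percentile
intervals are reported.  The default replicate count is 1,000,
overridable.

*VPC* simulates replicate datasets under the fitted model at the
original design, bins observations by time after the most recent dose
(decile edges by default; bins under 5 observations merge leftwards)
and overlays observed 5th/50th/95th percentiles on the simulated
percentile bands with their 95% CIs.  Note that the CI band width does
*not* shrink as the replicate count grows — the band is a predictive
interval across replicate datasets, not a standard error — so
convergence is monitored through calibration (coverage of the observed
percentiles), not band width.

*NPDE* decorrelates each subject's observed and simulated vectors with
the inverse Cholesky factor of the empirical simulation covariance
(ridge-regularised if singular, logged), computes rank-based prediction
discrepancies with the half-count correction 1/(2·n_sim) at the
extremes, and maps them through the standard-normal quantile.  Three
calibration tests are run: t-test for mean 0, a two-sided chi-square
dispersion test for variance 1 (the "variance = 1" test is reported by
some pharmacometric software under the Fisher label), and Shapiro–Wilk
normality; the global p-value is the Bonferroni (×3) adjustment of the
minimum, capped at 1, with the three raw p-values always reported
alongside.

*External validation* uses population predictions (η = 0): the
prior-free, stricter convention — no observed concentration of the
validation subject informs its prediction.  PE_j = 100·(PRED_j −
OBS_j)/OBS_j; MPE, MAPE and the inclusive fractions within ±20%/±30%
are reported.

## Dosing

At steady state AUC24 = daily dose/CL, so the dose for AUC24/MIC ≥ 400
at MIC 1 mg/L is 400·CL mg/day.  The initial-dose table simulates, per
(Scr, DFI, diuretic) cell, virtual neonates with weight uniform on
1–5 kg and η_CL ~ N(0, ω²), computes each patient's required per-kg
daily dose 400·CL/WT, and reports the cell median rounded half-up to an
integer mg/kg/day.  Residual (assay) error is excluded — steady-state
AUC depends on CL alone — while IIV on CL is included.  One common set
of random draws is shared across cells, which removes Monte-Carlo noise
from between-cell contrasts and makes the table's monotone structure
(doses fall with Scr, rise with DFI, diuretic column ≤ non-diuretic
column) exact.  How the 1–5 kg range was collapsed to one per-kg value
per cell is not uniquely determined by the source analysis; the
uniform-weight median rule used here is the simplest reading, and
because the per-kg dose rises with weight under a >1 weight exponent,
absolute cell values depend on that choice — the monotone structure and
the dose = 400·CL identity are the validated properties.

## Synthetic cohorts

Covariates are drawn from a Gaussian copula with log-normal margins
matched by (median, IQR) to the study's baseline table (weight median
1.98 kg, IQR 1.35–2.98; creatinine 32.48 µmol/L; daily fluid input
364 mL; etc.).  The only joint constraints honoured are the two
reported correlations, weight–PMA 0.8696 and weight–DFI 0.7274; latent
correlations are obtained by exactly inverting the log-normal Pearson
formula so the *observed-scale* correlations hit these targets.  The
unreported PMA–DFI correlation is filled by the conditional-independence
product through weight (a zero there is mathematically infeasible), and
any remaining non-PD matrix is repaired by eigenvalue clipping.  Binary
covariates are independent Bernoulli draws at the observed prevalences
(diuretic use 33.3%); the critical-illness score is a three-level
categorical.

The dosing rule draws one per-kg dose level per subject from
Uniform(10, 15) mg/kg (rounded to 0.5 mg per dose), an 8- or 12-h
interval with equal probability, 1-h infusions and six doses.  Sampling
attaches to the fifth dose — the first after the stated four-dose
run-in: one trough 0.5 h before it and one peak 0.5 h after its
infusion ends; 52% of subjects contribute the trough only, matching the
observed trough share of concentrations.  Simulated observations
outside 2–50 mg/L are flagged excluded (the flag never alters the
value), and subjects losing every observation are dropped.

What the generator does *not* emulate: time-varying covariates (values
are fixed at treatment start, as collected), irregular clinical
sampling times, dose adjustments during therapy, assay rounding, and
any covariate dependence beyond the two printed correlations.  Passing
recovery tests on these cohorts therefore demonstrates correctness of
the estimation machinery under the study's design, not robustness to
the messiness of real TDM data.  Distributional families are an
assumption (the baseline table reports only medians and IQRs);
log-normal margins are recorded in the configuration.

## Numerical choices and scale of the shipped experiments

Recovery experiments refit 112-subject cohorts (the study's modelling
size) over ten seeds; diagnostics calibration runs use reduced
replicate counts (tens of replicates, hundreds of simulations) and
smaller cohorts, with binomial three-sigma acceptance bands.  The test
suite's bootstrap examples use tens of replicates; the package default
remains 1,000.  Two estimation-level biases are visible at the study's
own scale and are properties of the design, not the code: with ~1.5
observations per subject the ω/σ split is weakly identified (ω̂ is
mildly inflated, σ̂ mildly deflated, their total variability well
determined — the split tightens at larger cohort sizes), and the
calibration filter truncates extreme residuals, shaving a few percent
off σ̂.  Degenerate inputs are validated eagerly: non-positive doses,
durations, concentrations and covariates, unknown enum values, and
malformed dataset rows raise typed errors naming the offender.

## Known limitations

Single residual-error level (no between-occasion variability); diagonal
Ω only; no censored-likelihood handling of out-of-range concentrations;
no prediction-corrected VPC; external validation does not Bayesian-update
on observed concentrations; two-compartment and nonlinear-elimination
structures are out of scope.
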