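# Methods

## Model

The package implements a shared-parameter joint model for a longitudinal
log cell count and competing time-to-event outcomes.

**Longitudinal submodel.** For subject *i* at time *t* (months since the
origin — transplant for model I, the early low-dose infusion for model II),
the observed log count is `y_ij = m_i(t_ij) + e_ij` with
`m_i(t) = x_i(t)'β + z_i(t)'b_i`, `e_ij ~ N(0, σ²)` independent, and
`b_i ~ N(0, D)`.  Counts below the assay detection limit of 0.5×10⁶/L are
set to the limit before taking natural logs; this only affects the earliest
visits, where counts are expected to be near zero after lymphodepletion.
The fixed design `x(t)` contains an intercept, a restricted cubic spline of
time, a CMV-pair level shift, and the full factorial expansion of
disease-risk group × donor type × spline-of-time (model I) or donor type ×
spline-of-time (model II, where all subjects are high risk).  Column order
is fixed and documented in `immunejm.lmm.design_column_names`.

**Spline basis.** Natural (restricted) cubic splines in the truncated-power
construction: with knots `k_1 < … < k_K` (boundary included), the columns
are `t` and `d_j(t) − d_{K−1}(t)`, `d_j(t) = [(t−k_j)₊³ − (t−k_K)₊³]/(k_K−k_j)`.
The first column is raw time; the basis is C² inside and exactly linear
outside the boundary knots, so extrapolation is linear.  Default knots:
interior at the 33.3%/66.7% quantiles of observed measurement times,
boundary at the 5%/95% quantiles (3 df).  The analysis of the undeposited
study data may have used different knots; every knot is config-overridable
and serialized with each fit.

**Event submodel.** Cause-specific proportional hazards
`h_ik(t) = h_0k(t) exp(γ_k'w_ik + α_k m_i(t) [+ η_k m_i'(t)])` with a
piecewise-constant baseline per cause.  The association coefficients α (and
slope coefficients η under the extended parametrization) are cause-specific
and the latent value m is measurement-error-free, so exp(α_k) is the hazard
ratio of cause k per unit log count.  Model I has three causes (GvHD,
relapse, other failure) with donor type and risk group as baseline
covariates, risk omitted for other failure (too few events); model II has
GvHD versus a relapse-or-other-failure composite, donor type only for GvHD.
Marker fits are univariate (one marker per joint fit); modelling several
markers jointly is out of scope — the exploratory two-marker question is
answered with a time-dependent-covariate Cox model instead.

**Likelihood.** The per-subject marginal likelihood integrates
`[∏_j N(y_ij | m_i, σ²)] · [∏_k h_ik(T_i)^{δ_ik}] · exp(−Σ_k Λ_ik(T_i))`
over `b_i ~ N(0, D)`.  Measurement truncation at the event time makes the
dropout informative exactly when α ≠ 0; maximizing the joint likelihood
therefore corrects both the trajectory estimates (for survivorship) and the
hazard ratios (for measurement error and heterogeneity).

## Numerics

* **Random-effects integral:** fully adaptive Gauss–Hermite quadrature.
  For each subject the posterior mode of `b` is found by damped Newton
  (analytic gradient and Hessian, vectorized across subjects, tolerance
  1e-10), the integrand is recentred and rescaled by the mode curvature,
  and a product GH rule (default order 9 per dimension; weight-threshold
  pruned above two dimensions) is applied.  At zero association the rule is
  exact for the Gaussian integrand, which yields the factorization identity
  tested in the acceptance suite.
* **Cumulative hazards:** fixed-order Gauss–Legendre (default 15) applied
  piecewise between the baseline cut-points, clipped at the subject's event
  time, so the piecewise-constant baseline introduces no quadrature error
  at its jumps.
* **Baseline cut-points:** shared across causes (a union grid supports
  per-cause cuts); defaults at all-cause event-time quantiles with five
  intervals, fewer when events are sparse (at least three events per
  interval for the rarest cause).
* **Optimization:** BFGS on unconstrained transformed parameters (log σ,
  log-Cholesky of D, log baseline levels) with forward-difference
  gradients (per-parameter step 3e-6·(1+|θ|)).  Initialization is
  two-stage: the mixed model alone (statsmodels MixedLM, ML), then
  cause-specific Cox fits on segment-wise intervals carrying the
  empirical-Bayes current value, then Breslow-style baseline levels.  With
  finite-difference gradients the attainable gradient norm is limited by
  cancellation (≈1e-3 on these likelihoods); the optimizer's
  "precision-loss" stop with a small remaining gradient is treated as
  convergence, and the final gradient norm is reported in `diagnostics_`.
  Fits are deterministic given data and settings.
* **Standard errors:** inverse of the observed information obtained by
  central finite differences of the log-likelihood (step 1e-4·(1+|θ|));
  Wald 95% intervals `exp(est ± 1.96·SE)` for hazard ratios.
* **Degenerate inputs:** subjects without measurements contribute only
  their marginal survival probability; causes without events abort the fit
  with a clear error; non-positive-definite initial covariances are
  eigenvalue-floored.

## Synthetic cohorts

The generator defines the verification conditions and emulates: cohort
composition (166 subjects; 62/166 high risk, 109/166 unrelated donors with
ATG, 51/166 CMV −/− pairs); a CD4-like reference trajectory rising from the
detection floor to ≈180×10⁶/L by six months, an ATG effect depressing early
counts by ≈2 log units with catch-up, a post-infusion divergence of the
high-risk × unrelated-donor cell after month three, and a +0.11 CMV level
shift; lognormal measurement error (σ = 0.5) around the latent trajectory
with the 0.5×10⁶/L floor; jittered scheduled visits (eight nominal visits,
jitter SD 0.15, missed-visit probability 0.10 — chosen so that the median
number of measurements per subject is 6 with IQR ≈ [5, 7], matching the
reported visit summary once event truncation is accounted for; a sparser
7-visit schedule undershoots the median); and event times drawn by exact
inverse-transform sampling of the generative cause-specific hazards (Brent
root-finding on the all-cause cumulative hazard, Gauss–Legendre inner
integrals, tolerance 1e-8 months; a mathematically identical vectorized
safeguarded-Newton sampler serves large Monte-Carlo checks and is tested
for agreement with the scalar path).  Baseline hazard levels and covariate
log-hazard-ratios were calibrated once, by iterative simulation, to the
study's regime — six-month GvHD incidence ≈26%/≈5% by risk group, relapse
≈15%, other failure ≈18%, with event times spread over the window — and
frozen; the association coefficients default to α = (0.89, −0.43, −0.36),
the log hazard ratios of the strongest reported associations.

What the generator does *not* emulate: CMV reactivation episodes and their
transient count spikes, chimerism, cross-correlated multi-marker dynamics
(the optional second marker is independent by construction), visit-time
dependence on clinical state, and heavy-tailed measurement error.  Passing
tests therefore demonstrate the estimator's correctness under the model's
own assumptions plus realistic sizes and rates — not robustness to the
ways real registry data violate those assumptions.

## Default problem sizes

Joint fits in the pipeline and the acceptance script use a
random-intercept-plus-linear-time random-effects structure (d = 2), GH
order 7–9 and GL order 9–15.  The standalone mixed model defaults to the
richer intercept-plus-all-spline-columns structure; for the joint fits the
d = 2 default is a deliberate accuracy/cost choice — it captures the
level and recovery-rate heterogeneity that drives the association
estimates, while d = 4 adaptive quadrature is supported but roughly an
order of magnitude slower.  Simulation studies in the test suite use 50
replicates of n = 300 (bias and coverage of α) and 200 replicates of
n = 80 (type-I error of the slope test); these sizes give Monte-Carlo
standard errors comfortably inside the asserted bands.

## Known limitations

* Hazard ratios from single cohorts at the study's size (n = 166, ≈20–30
  events per cause) carry wide confidence intervals; the replicate studies,
  not any single simulated cohort, establish unbiasedness.
* The Wald slope test is slightly conservative at small n; the
  likelihood-ratio variant is also provided.
* No Bayesian estimation, no dynamic (landmark) prediction, no
  subdistribution (Fine–Gray) hazards, no multivariate joint model.
* The LOCF counting-process Cox attenuates associations relative to the
  joint model (stale covariate values plus measurement error); it is an
  exploratory adjunct, mirrored in the two-marker acceptance check.
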