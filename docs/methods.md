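# Methods

`trajsurv` implements two joint models for a longitudinal biomarker and a
right-censored time-to-event, applied here to transformed CD4 counts and
time from HIV diagnosis to death, plus the machinery needed to compare
them as dynamic prognostic tools.

## Data model

The cohort is a pair of tables: long-format measurements (subject, time in
years since diagnosis, CD4 in cells/mm³) and subject-level records (time
to death or censoring, event indicator, sex, addiction, age at diagnosis).
The marker is modeled on a root scale — `fourth_root` by default,
`square_root` by configuration — because CD4 counts are strongly
right-skewed; both transforms are strictly increasing, so the fitted
models are transform-agnostic in structure. Covariate coding is fixed:
`sex` 1 = female, `addiction` 1 = no history of addiction, age in years,
constant from baseline. Eligibility follows the registry rule of at least
two measurements (`filter_eligible`, threshold configurable); measurements
recorded after the event/censoring time are dropped with a warning rather
than rejected, which is the common state of registry extracts.

All likelihoods consume per-subject sufficient statistics (visit count and
the moments of `(t, y)`), so likelihood evaluation cost is independent of
the number of measurement rows once the statistics are built.

## Shared random-effect model (SREM)

Longitudinal sub-model: linear mixed model on the transformed marker with
random intercept and slope, `(b0, b1) ~ N(0, B)`, residual variance σ².
Survival sub-model: Weibull proportional hazards with baseline
`λ0(t) = (ρ/σ_w)(t/σ_w)^(ρ-1)` (so `Λ0(t) = (t/σ_w)^ρ`; no single
convention is universal, so this one is fixed package-wide — rate
parameterizations convert via `λ = 1/σ_w`),
covariates (sex, addiction, age), and association terms `α4·b0 + α5·b1`
added to the log hazard. Because the association is constant in time, the
conditional log-likelihood given `b` is concave (quadratic + linear −
exponential of a linear form): each subject's conditional mode is found by
a damped Newton iteration with a closed-form 2×2 solve, and the marginal
likelihood uses adaptive Gauss–Hermite quadrature centered and scaled at
the mode. Nine nodes per dimension is the default; with `α4 = α5 = 0` the
integrand is exactly Gaussian and the quadrature is exact for any node
count, which provides one of the cross-checks in the test suite (the other
is plain Monte-Carlo integration).

Maximization is a Levenberg–Marquardt-damped Newton on the log-likelihood
with numerically differenced derivatives, warm-started by an L-BFGS-B pass
(first at 5 quadrature nodes, then at the requested node count — the
adaptive quadrature is node-insensitive near the optimum, so the coarse
phase only locates it). Convergence requires relative log-likelihood
change ≤ 1e-5, parameter change ≤ 1e-4 and the scaled gradient criterion
`g'H⁻¹g/P ≤ 1e-3` simultaneously; non-convergence flags the result rather
than raising. Positivity and positive-definiteness are enforced by
optimizing log(ρ), log(σ_w), log(σ) and the log-Cholesky factor of B.
Standard errors come from the inverse observed information (numerical
Hessian) on that unconstrained scale; reported Wald intervals for
variance-type parameters are therefore log-scale intervals.

Initialization is two-stage: pooled least squares for the fixed effects,
per-subject OLS lines for the variance components, a covariates-only
Weibull PH fit for the survival part, and zero association.

## Joint latent class model (JLCM)

The population is a finite mixture of G latent classes: multinomial
logistic membership on (intercept, sex, addiction, age) with the last
class as reference; class-specific trajectory intercept and slope with
common covariate effects, common random-effect covariance B and residual
variance; and a Weibull hazard with common covariate effects scaled by a
class-specific proportional factor `exp(ξ_g)`, `ξ_G = 0`. The class factor
is the minimal structure consistent with class-specific survival curves
and with one extra hazard parameter per class in the parameter count
`P = 14 + 7(G-1)`. Conditional on class, the random effects integrate out
of the longitudinal normal in closed form (Woodbury identities on the 2×2
matrix `σ²B⁻¹ + Z'Z`), so the mixture log-likelihood is exact — no
numerical integration anywhere in this family.

Fitting uses multiple structured starts: subjects are partitioned by
k-means on per-subject (level, slope) features, by level quantiles and by
slope quantiles; further starts jitter the class-specific blocks. The
slope features are precision-shrunken toward the pooled slope and
winsorized, because raw OLS slopes from two or three close visits are
extremely noisy. Crucially, the start's random-effect covariance is
estimated from *within-group* deviations: the pooled single-class
estimate absorbs the between-class variance and reliably drags the
optimizer into a spurious mode in which inflated random effects wash out
the classes. Each start gets a short quasi-Newton run; the best are
optimized fully (the Marquardt path above). `polish=False` skips the
damped-Newton finish for enumeration batteries where only the maximized
log-likelihood is needed. Fitted classes are reported in canonical order
(descending ξ, "high risk" first); the reference shift is absorbed into
the Weibull scale so the likelihood is unchanged.

### Class-number selection

Models with G = 1..4 are fitted; `BIC = -2·loglik + P·log(n)` is computed
for each; the selected model is the lowest-BIC candidate whose
conditional-independence test (below) is not rejected at α = 0.05. If all
candidates are rejected the BIC minimum is returned with a warning.

### Conditional-independence score test

The JLCM assumes the marker and the event are independent given class. The
test augments the within-class hazard with loadings γ of the random
effects and scores H0: γ = 0 at the fitted null model. The per-subject
score has the closed form
`Σ_g w_ig (δ_i − Λ_ig(T_i)) E[b | Y_i, c_i = g]` — posterior class weight
times class martingale residual times the empirical-Bayes random-effect
mean. The statistic is the efficient (Rao) score with empirical
outer-product information, projecting out the estimated-parameter block
(per-subject parameter scores are numerically differenced); reference
distribution χ² with df = 2 (one per random effect). Outer-product
information is biased low in small samples, so the variance carries the
standard `n/(n−k)` degrees-of-freedom correction (k = estimated parameters
plus tested loadings). Pseudo-inverses guard against rank deficiency at
degenerate fits, and one-sided differences take over when a fit sits on a
variance boundary. Type-I error of this variant
is checked by simulation in the test suite; the exact estimator used in
any particular software implementation of such tests is not reproducible
from published statistics alone, so only the χ²₂ mapping is treated as
exact.

## Dynamic prediction

For a subject event-free at landmark s, the risk in `(s, s+t]` given the
marker history up to s:

- JLCM: closed form, `Σ_g w_g(s) [S_g(s) − S_g(s+t)] / S_g(s)` with
  `w_g(s) ∝ π_g(x) · f(Y_history | g) · S_g(s)`. An empty history is
  allowed (weights reduce to prior × survival).
- SREM: the window risk averaged over the posterior of `b` given the
  history *and survival to s* (the probabilistically correct
  conditioning), by the same adaptive quadrature; a posterior-mode plug-in
  is available as a fast option. Both reduce to the covariate-only Weibull
  window risk when `α4 = α5 = 0`, which is also the exact coherence point
  with a single-class JLCM.

Ties at the landmark: a measurement at exactly s belongs to the history;
an event at exactly s removes the subject from that landmark's risk set.
Default grid: s = 1, 1.5, …, 8 years (15 landmarks), window t = 3 years.

## Accuracy comparison

At each landmark, cases are deaths in `(s, s+t]`, controls are subjects
followed beyond `s+t`, and subjects censored inside the window are
excluded from both groups (simple landmark estimator; an IPCW-weighted
variant with Kaplan–Meier censoring weights is available behind a flag for
sensitivity analysis). AUC(s, t) is the Mann–Whitney concordance of the
dynamic risks with ties counted 1/2, computed from tie-averaged ranks and
verified against exhaustive pairwise comparison; the ROC construction
yields a trapezoidal area identical to the concordance. The summary
"average AUC" is the unweighted mean over landmarks with a defined AUC.

## Synthetic cohorts

The generator draws covariates (18.3% female, 30% with no addiction
history, age ~ N(38, 8²) truncated above 18 years), latent structure
(classes from the membership model, random effects from B), event times by
exact inverse-transform sampling of the Weibull PH survival function
(valid because all latent terms enter the hazard as time-constant
multipliers), independent exponential censoring (rate 0.24/year) plus a
25-year administrative horizon, and visits every 0.5 years with Gaussian
jitter (SD 0.08 y) truncated at follow-up. Markers are the model mean plus
N(0, σ²) noise on the transformed scale, floored at zero.

Defaults emulate the motivating registry cohort: 213 subjects, ~24%
deaths, median 5 visits and ~6.8 measurements per subject. Parameters the
study context does not pin down were fixed once: residual variance 0.16
(SD 0.4 on the fourth-root scale, typical of CD4 trajectory fits),
random-effect covariance `[[0.466, −0.0194], [−0.0194, 0.009]]`
(variances as reported for such cohorts, correlation −0.3), addiction
prevalence 0.30, and Weibull baselines (shape 1.1; scales 2.0 for the
shared-random-effect truth and 34.0 for the 3-class truth) calibrated to
the ~24% event fraction under the visit/censoring design.

Two 3-class truths are provided. `default_jlcm_params` uses published
estimate-scale values and is moderately separated. `separated_jlcm_params`
is the well-separated experimental scenario: tight random effects
(`B = [[0.16, −0.008], [−0.008, 0.004]]`, σ² = 0.10), strongly distinct
trajectories (intercepts 3.8/5.0/6.2, slopes −0.35/−0.175/0.0), and class
mortality deliberately **non-monotone** in the trajectory (ξ = 1.5/2.7/0:
the moderate-trajectory class carries the highest hazard). The
non-monotonicity is a design finding of this package: when class risk is
monotone in trajectory level/slope, a shared-random-effect model's linear
association score ranks subjects essentially as well as the true
latent-class predictor, and the two frameworks' landmark AUCs are
indistinguishable; the latent-class model's discriminative advantage is
specific to heterogeneity *not mediated by* the biomarker's level or
slope — precisely the unobserved-risk-factor heterogeneity that motivates
latent-class joint models. Tests of the "JLCM beats SREM" direction
therefore use this scenario.

What the generator does not emulate: informative visit processes and
informative dropout (censoring is independent), cause-of-death
adjudication (other-cause deaths are encoded upstream as censorings),
measurement-batch effects, and time-varying covariates. Passing tests
demonstrate correctness of the estimators under the models' own
assumptions at these design points, not robustness to real-registry
violations of them.

A note on eligibility filtering in simulations: the ≥2-measurement rule
conditions retention on surviving to the second visit, a left-truncation
selection that biases an unconditional likelihood. Parameter-recovery
experiments therefore fit on cohorts filtered with `min_measurements=1`
(every subject has a baseline visit), where the MLE is unbiased by
construction; the ≥2 rule remains the data-model default for real-data
workflows.

## Problem sizes and numerical choices

Simulation-based checks run at the sizes a desk machine handles in
minutes: 20 replicate fits at n = 500 (SREM) and n = 600 (2-class JLCM)
for Wald coverage; 200 null cohorts at n = 150 for score-test
calibration; 20 cohorts at n = 600 for BIC selection; one n = 600 cohort
for the model-comparison direction. Monte-Carlo oracles use 1e5 draws.
Tolerances: closed-form identities at 1e-6–1e-12; Monte-Carlo agreements
at 3 standard errors; quadrature node-doubling as a convergence
diagnostic. Degenerate inputs (empty histories, empty classes, singular
information) return flagged or NaN results rather than raising wherever a
flagged result is meaningful.

## Known limitations

- The score-test variance uses outer-product information; observed-minus-
  expected variants would differ in small samples.
- No competing risks: other-cause deaths must be encoded as censorings.
- No current-value/current-slope association structures for the SREM, no
  spline trajectories or baselines, and no class-specific residual
  variances or covariance scales.
- Individual dynamic risks are point predictions without uncertainty
  intervals.
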