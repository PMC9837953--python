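# Methods

## Model structure

Observation of patient *i* is an alternating two-state process over follow-up
*T_i*: exacerbation-free ("healthy") sojourns `B_{i,1}, B_{i,2}, ...` and
exacerbation sojourns `W_{i,1}, W_{i,2}, ...`, each completed episode carrying
a binary severity mark `S_{i,j}`. The first healthy sojourn is measured from
randomization: the (unknown) termination of any pre-study exacerbation is set
to time zero. This ignores left-truncation of the first gap; the
approximation is benign exactly when the fitted baseline hazard of the rate
submodel is close to constant, which should be checked on any application.

Conditional on a trivariate patient-level random effect
`Z_i = (Z_B, Z_W, Z_S) ~ MVN(0, Sigma_Z)`:

* between-gaps follow an AFT law `log B = x'beta_B + Z_B + eps_B`,
* durations follow `log W = x'beta_W + Z_W + eps_W`,
* severities are Bernoulli with `logit p = x'beta_S + Z_S`,

and, given `Z_i`, the `B`'s are independent of the `(W, S)` pairs, gaps of
each kind are mutually independent across episodes, and `W` and `S` are
independent of each other given the episode occurred. A latent
non-susceptible class with probability `logit pi_i = x_0'beta_ZI` (baseline
covariates only, no random effect) mixes with the susceptible process to
absorb excess zero-event patients. Subjects are independent; dropout
censoring is assumed independent of the outcome processes.

The marginal likelihood of a subject is therefore

```
M = 0:    pi + (1 - pi) * E_Z [ S_B(T | x, Z_B) ]
M >= 1:   (1 - pi) * E_Z [ prod_j f_B(B_j) * f_W(W_j) * p_j^{S_j} (1-p_j)^{1-S_j}
                           * S_B(final gap) ]
```

with a survival factor replacing `f_W` for a within-censored episode. Only
the final between-gap is censored in the default convention; the
`within_censored` flag extends the likelihood to designs that stop
mid-episode.

### Error-law parametrizations

Coefficient vectors carry an explicit leading intercept, so the family shape
is purely a scale parameter (one "shape" number per gap submodel):

| family       | eps law                                   | shape sigma        |
|--------------|-------------------------------------------|--------------------|
| lognormal    | Normal(0, sigma^2)                        | residual SD of log-time |
| loglogistic  | Logistic(0, sigma)                        | logistic scale     |
| weibull      | exp(eps) ~ Weibull(1/sigma, 1)            | 1 / Weibull shape  |
| exponential  | Weibull with sigma fixed at 1             | none (fixed)       |

In every family `S(t | eta + b) = S(t e^{-b} | eta)` exactly: `exp(beta)`
multiplies the expected event time (the AFT factor). A positive coefficient
in the rate submodel means longer gaps, i.e. a *lower* exacerbation rate.

### Random-effects parametrization

`Sigma_Z` is optimized unconstrained: three log-SDs plus three reals mapped
through canonical partial correlations (`tanh`, then a Cholesky walk) to a
correlation matrix. Every real input yields a symmetric positive-definite
covariance, so the optimizer never needs constraints; the transform
round-trips to machine precision. Submodels can be configured without a
random effect; the corresponding rows/columns are dropped from `Sigma_Z`.

## Numerical integration

The random-effect integral uses tensor-product Gauss–Hermite quadrature,
default 5 points per dimension (125 nodes for subjects with events, 5 for
zero-event subjects, whose integrand depends only on `Z_B` and is integrated
in one dimension against its normal marginal — exact dimension reduction, not
an approximation).

In the default *adaptive* mode the grid is recentred per subject at the
posterior mode of `Z` and rescaled by the inverse Cholesky factor of the
negative log-posterior Hessian. Because every conditional term involves a
single component of `Z` and each term is log-concave in its linear
predictor, the conditional log-likelihood has a *diagonal* Hessian in `Z`
with closed-form entries; the mode search is a damped Newton iteration with
analytic first and second derivatives, warm-started across likelihood
evaluations. If the negative Hessian fails its Cholesky factorization
(never observed in testing — concavity guarantees positive definiteness up
to round-off) the code falls back to the fixed Sigma-scaled grid. All
mixture and quadrature sums run through log-sum-exp.

Measured convergence on a realistic fixture (300 subjects, severity RE SD
1.5): refining the adaptive rule from 5 to 9 points changes per-subject
log-likelihoods by at most ~6e-4 (total ~0.015), 9 to 13 by ~2e-5 total,
and 13 to 21 by ~2e-8. The 5-point default is therefore accurate to far
below statistical noise for estimation, while not literally exact; the
independent Monte-Carlo oracle (200k draws) agrees within sampling error.

## Estimation and inference

The free vector (coefficients, log shapes, log RE SDs, correlation reals) is
maximized by BFGS with finite-difference gradients from stage-wise starting
values: fixed-effects AFT fits on the pooled between-gaps (with censoring)
and durations, a plain logistic fit on severities, a logistic fit of the
zero-event indicator for the ZI component (an upward-biased but serviceable
start for `pi`), RE SDs at 0.5 and correlations at 0. Separation in the
logistic starts falls back to a +/-10-capped logit intercept.

Convergence is declared at gradient max-norm below `max(1e-3, 1e-6 |loglik|)`
or relative log-likelihood change below 1e-9 (maximum 500 iterations). The
relative component reflects the finite-difference noise floor, which scales
with the objective; demanding a fixed 1e-5 at a log-likelihood of order 1e4
is below what FD gradients can resolve. Non-convergence is always flagged,
never silent, and non-converged candidates are excluded from AIC rankings
with a warning.

Standard errors come from the inverse of a central finite-difference Hessian
(relative step 1e-3) of the negative log-likelihood at the optimum; a
non-positive-definite Hessian marks the vcov unavailable rather than
fabricating intervals. Reported tables exponentiate coefficients and their
95% Wald limits (AFT factors / odds ratios). RE SD intervals are formed on
the log scale, correlation intervals on the Fisher-z scale via the delta
method (finite-difference gradient of the transform), guaranteeing
back-transformed intervals inside (-1, 1). AIC counts every free parameter
of the configured model; disabled components contribute none. The 0.05
significance flag is presentational; no multiplicity adjustment is applied.

Episode-specific covariates are derived, not stored: at the onset of the
j-th exacerbation-free period, `n_prior = j - 1` completed exacerbations and
`n_prior_severe` their severe subset; the final censored gap uses the totals
over all completed episodes. The generator applies exactly the same rule, so
simulation and fitting are mutually consistent by construction.

## Empirical-Bayes prediction

The EB estimate is the posterior *mode* of `Z` given the subject's data
(consistent with the predictor typical of nonlinear mixed-model software;
for non-Gaussian posteriors mode and mean differ slightly). For zero-event
subjects only `z_B` is identified; duration/severity components are returned
as NaN. Marginal predicted means use
`E[exp(eta + z + eps)] = exp(x'beta) E[exp(eps)] E[exp(z)]` with closed-form
`E[exp(eps)]` per family (`exp(sigma^2/2)` log-normal, `Gamma(1+sigma)`
Weibull, `pi sigma / sin(pi sigma)` log-logistic — infinite for sigma >= 1,
reported as `+inf`) and `E[exp(z)] = exp(sigma_z^2/2)`; a conditional
variant plugs in the EB estimate instead. Both are exposed because "mean
predicted outcome" is ambiguous between the two in routine use.

## Goodness of fit: marginal CDF curves

The model-implied marginal CDF of a gap time is averaged over the realized
covariate rows of the dataset, integrating the random effect by 41-point
Gauss–Hermite quadrature per row; the observed curve is 1 minus the
Kaplan–Meier estimate on the pooled gaps (censored final gaps enter as
censored). For the between-gap curve a switch controls the zero-inflation
weight: conditional on susceptibility (default, the natural "gap
distribution of exacerbators" view) or unconditional, multiplying each
subject's CDF by `1 - pi_i`.

A caveat that the validation studies quantify: the pooled-gap KM comparison
carries *systematic* slack even when the model is exactly true. Frequent
exacerbators contribute more gaps, and their frailties are informative, so
the pool is a length-biased, cluster-correlated sample; the cure fraction
additionally dilutes risk sets, and later gaps are subject to induced
dependent censoring. Measured at the generating parameters with ~1500-3000
pooled gaps, sup distances are ~0.02 with no random effects (pure sampling
noise) but 0.05–0.11 under the realistic frailty scenario. The closure check
therefore uses a 0.15 band — a guard against gross misfit (wrong family,
wrong scale), not a calibrated KS test — while the *first-gap* comparison,
which is free of pooling bias, closes within a conventional KS-style band
(< 0.05) and is tested separately.

## The synthetic-data generator

The generator emulates the structure of a pooled pair of exacerbation
trials; it is the test bed for every other module and makes no claim to
reproduce any real dataset. Per subject: baseline covariates are drawn from
the configured spec; a non-susceptibility indicator from `Bernoulli(pi_i)`;
`Z` from `MVN(0, Sigma_Z)`; an independent exponential dropout time; then
susceptible subjects alternate gap draws (inverse-CDF on the log scale,
exact for every family) with severity Bernoullis, updating `n_prior` /
`n_prior_severe` as they go. Observation stops at the minimum of nominal
follow-up and dropout; a subject mid-episode at that point is followed to
the episode's end (the final gap is then zero), or, if that convention is
disabled, the episode is recorded with a censored duration. The final
partial between-gap is recorded censored. A guard errors out beyond 10^4
episodes per subject as a parameter-sanity check.

The default scenario (`default_case_study_config`) is a two-arm,
two-horizon (347/224-day) trial mix of ~1100 subjects with three baseline
covariates (treatment Bernoulli(0.5); age in decades ~ N(4.9, 1.3); female
Bernoulli(0.6)), log-normal families (shapes 1.2 / 0.62), a treatment AFT
factor of 2.0 on the rate submodel, RE SDs (0.8, 0.5, 1.5) with
correlations (0.4, 0.45, 0.45), zero-inflation around one third, and
dropout hazard 4e-4/day — yielding roughly half zero-event subjects, ~14-day
mean durations and ~15% severe episodes, the magnitudes typical of this
disease area. The severity intercept (-1.4) was set so the marginal severe
fraction lands near that target given the age effect on the decades scale.

What the generator does *not* emulate — and what passing tests therefore do
not establish about real data: left-truncation of the first gap, covariate
measurement error and missingness, informative dropout, calendar-time or
season effects, competing risks (death), ordinal severity, and
non-normal random effects.

## Validation studies and problem sizes

`rdsjoint.studies` packages the validation experiments; the test-suite and
`scripts/acceptance.py` both drive them. Problem sizes are chosen to give
clear verdicts at interactive runtimes on one CPU: 5 subjects x 200k draws
for the Monte-Carlo integration check (3-SE agreement); 5 replicates of
n = 1000 for Wald coverage (aggregate coverage across all parameters
compared with the nominal 95% under binomial noise); n = 400 for the
degenerate-collapse identity against independent lifelines/statsmodels fits
(agreement to < 1e-4, typically < 1e-8); 5 replicates of n = 300 for AIC
family selection (log-normal truth should win >= 4/5); n = 1000 (~2000
pooled gaps) for the CDF closure bands above.

## Known limitations

* The first between-gap is treated as fully observed from randomization
  (no left-truncation correction).
* Baseline hazards are parametric; no spline/piecewise option.
* Severity is binary; no ordinal extension.
* No competing risks; dropout is assumed independent.
* Wald inference only (no profile likelihood or bootstrap); vcov quality
  depends on the finite-difference Hessian at the optimum.
* RE SDs at or near zero sit on the parameter-space boundary; estimates
  shrink toward zero without error, but Wald intervals there are unreliable
  (standard boundary caveat).
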