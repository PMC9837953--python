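# rdsjoint

Joint parametric modelling of the **rate**, **duration**, and **severity** of
recurrent disease exacerbations.

Many chronic diseases — asthma, COPD, multiple sclerosis, cystic fibrosis —
progress through episodic flare-ups (exacerbations). Their total burden has
three dimensions: how *often* they occur, how *long* they last, and how
*severe* they are. Most analyses model only the event rate; `rdsjoint`
implements a joint model for all three, for biostatisticians and trialists
who want simultaneous, internally consistent inference on every dimension
(e.g. "does the treatment shorten exacerbations as well as delay them?") and
on how the dimensions interrelate across patients.

## The model

Follow-up of patient *i* is an alternating two-state process: exacerbation-
free gaps *B*<sub>i,j</sub> (between-gap times, governing the rate), episode
durations *W*<sub>i,j</sub> (within-gap times), and a binary severity mark
*S*<sub>i,j</sub> per episode. The first gap is measured from randomization
(*V*<sub>i,0</sub> ≡ 0); the final between-gap is censored at the end of
follow-up, and a patient mid-episode at the nominal end of follow-up is
followed to that episode's termination.

Four submodels share correlated patient-level random effects
**Z**<sub>i</sub> = (Z<sub>B,i</sub>, Z<sub>W,i</sub>, Z<sub>S,i</sub>)ᵀ ~
MVN(0, Σ<sub>Z</sub>):

* **Rate** — accelerated failure time (AFT) with random effect:
  log *B*<sub>i,j</sub> = **x**ᵀ<sub>i,j</sub>**β**<sub>B</sub> + Z<sub>B,i</sub> + ε<sub>B</sub>;
* **Duration** — AFT likewise for log *W*<sub>i,j</sub>;
* **Severity** — logistic: logit P(*S*<sub>i,j</sub>=1) =
  **x**ᵀ<sub>i,j</sub>**β**<sub>S</sub> + Z<sub>S,i</sub>;
* **Zero-inflation** — a latent non-susceptible (cure) class with
  logit π<sub>i</sub> = **x**ᵀ<sub>i,0</sub>**β**<sub>ZI</sub> (baseline
  covariates only, no random effect), absorbing the excess of zero-event
  patients.

Baseline hazards come from the exponential, Weibull, log-normal or
log-logistic family, selected by AIC. `exp(β)` is the **AFT factor** — the
multiplier of the expected time to event per unit covariate — for the gap
submodels, and an odds ratio for the logistic submodels. The marginal
likelihood integrates the random effects by adaptive Gauss–Hermite
quadrature (one-dimensional for zero-event patients, whose conditional
likelihood involves only Z<sub>B</sub>); estimation is maximum likelihood
with Wald inference from the observed information. Empirical-Bayes random
effects are posterior modes given each patient's data.

## Worked example

```python
import numpy as np
from rdsjoint import default_case_study_config, simulate_dataset, pack_dataset, fit

cfg = default_case_study_config(n_subjects=400)   # two-arm trial-like scenario
subjects, truth = simulate_dataset(cfg, seed=1)
print(f"subjects: {len(subjects)}, exacerbations: {sum(s.n_episodes for s in subjects)}, "
      f"zero-event fraction: {np.mean([s.n_episodes == 0 for s in subjects]):.3f}")
result = fit(pack_dataset(subjects, cfg.model), cfg.model)
print(result.summary())
```

prints (abridged):

```
subjects: 400, exacerbations: 448, zero-event fraction: 0.537
Joint RDS model fit: 400 subjects, loglik -4370.897, AIC 8789.793, converged

[rate]
  covariate     coef       se  AFT factor    ci_low   ci_high  significant
(intercept) 3.704600 0.365284   40.633799 19.858993 83.141461         True
  treatment 0.437701 0.181825    1.549142  1.084730  2.212384         True
...
[random effects]
             parameter  estimate    ci_low  ci_high
               SD rate  0.747564  0.568804 0.982503
           SD duration  0.495149  0.409313 0.598985
           SD severity  1.621735  1.026101 2.563124
    corr rate-duration  0.403406  0.103014 0.636364
...
```

The treatment AFT factor of 1.55 (95% CI 1.08–2.21) on the rate submodel
estimates the generating factor of 2.0: treated patients' expected
exacerbation-free gaps are stretched, i.e. their event rate is lower. The
duration AFT factor 0.81 (0.66–0.98) says treated episodes are ~19% shorter.
The random-effect SDs (generating values 0.8 / 0.5 / 1.5) quantify
between-patient heterogeneity beyond the covariates, and the positive
rate–duration correlation (0.40 here) says patients with longer gaps (slower
rates) tend to have longer episodes.

A command-line interface wraps the same workflow:

```bash
rdsjoint simulate --n-subjects 400 --seed 1 --out data.csv
rdsjoint fit --data data.csv --out results/ --family lognormal
rdsjoint select-family --data data.csv
rdsjoint predict --data data.csv --out pred/
```

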