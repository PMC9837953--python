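"""Reusable simulation studies: integration accuracy, parameter recovery,
degenerate-model collapse, family selection, and goodness-of-fit closure.

These are the package's own validation experiments — the simulation-study
workflow a methods paper in this area would run — packaged as functions so
they can be driven both from the test-suite and from reproduction scripts.
All randomness flows from an explicit integer seed.
"""

from __future__ import annotations

from dataclasses import replace

import numpy as np
import pandas as pd

from .config import ModelConfig
from .estimation import ParameterLayout, fit, select_family
from .likelihood import (
    make_quadrature,
    marginal_subject_loglik,
    mc_marginal_subject_loglik,
    pack_dataset,
    subject_logliks,
)
from .model_core import ModelParameters, re_covariance_to_unconstrained
from .prediction import cdf_sup_distance
from .simulate import (
    CovariateSpec,
    SimulationConfig,
    default_case_study_config,
    simulate_dataset,
)

__all__ = [
    "quadrature_vs_monte_carlo",
    "parameter_recovery",
    "degenerate_collapse",
    "family_selection_study",
    "cdf_closure",
]


def quadrature_vs_monte_carlo(seed: int = 0, n_draws: int = 200_000,
                              max_episodes: int = 4) -> pd.DataFrame:
    """Adaptive-quadrature marginal log-likelihood vs a Monte-Carlo estimate.

    Picks five synthetic subjects with episode counts spread over
    0..`max_episodes` and returns per-subject quadrature value, MC estimate,
    MC standard error and the standardized discrepancy z = (quad - mc) / se.
    """
    cfg = default_case_study_config(n_subjects=400)
    subjects, _ = simulate_dataset(cfg, seed=seed)
    by_m = {}
    for s in subjects:
        by_m.setdefault(min(s.n_episodes, max_episodes), s)
    picks = [by_m[m] for m in sorted(by_m)][:5]
    rule = make_quadrature(5, "adaptive")
    rng = np.random.default_rng(seed + 1)
    rows = []
    for s in picks:
        quad = marginal_subject_loglik(s, cfg.true_params, rule, cfg.model)
        mc, se = mc_marginal_subject_loglik(s, cfg.true_params, cfg.model,
                                            n_draws, rng)
        rows.append({"subject_id": s.subject_id, "n_episodes": s.n_episodes,
                     "quad": quad, "mc": mc, "mc_se": se,
                     "z": (quad - mc) / se})
    return pd.DataFrame(rows)


def parameter_recovery(n_subjects: int = 1000, n_replicates: int = 5,
                       seed: int = 0) -> dict:
    """Simulate-and-refit study on the case-study-like scenario.

    Each replicate simulates `n_subjects` subjects at the generating
    parameters (log-normal families, RE SDs 0.8/0.5/1.5, correlations
    0.4/0.45/0.45, treatment AFT factor 2 on the rate submodel), fits the
    joint model, and records whether each true parameter lies inside its 95%
    Wald interval.  Returns the coverage matrix plus summaries.
    """
    base = default_case_study_config(n_subjects=n_subjects)
    layout = ParameterLayout(base.model)
    truth = layout.to_vector(base.true_params)
    cover = np.zeros((n_replicates, layout.n_free), dtype=bool)
    treat_aft = []
    converged = []
    for rep in range(n_replicates):
        subjects, _ = simulate_dataset(base, seed=seed + 1000 * rep + 1)
        fr = fit(pack_dataset(subjects, base.model), base.model)
        converged.append(fr.converged)
        se = np.sqrt(np.diag(fr.vcov)) if fr.vcov is not None else np.full(
            layout.n_free, np.nan)
        cover[rep] = np.abs(fr.theta_hat - truth) < 1.959964 * se
        treat_aft.append(float(np.exp(
            fr.theta_hat[layout.names.index("rate:treatment")])))
    per_param = cover.mean(axis=0)
    return {
        "param_names": list(layout.names),
        "coverage_matrix": cover,
        "per_parameter_coverage": per_param,
        "aggregate_coverage": float(cover.mean()),
        "min_parameter_coverage": float(per_param.min()),
        "treatment_aft_factors": treat_aft,
        "converged": converged,
        "n_replicates": n_replicates,
        "n_subjects": n_subjects,
    }


def _collapse_scenario(seed: int, n_subjects: int = 400):
    model = ModelConfig(
        rate_covariates=["treatment", "age_decades"],
        duration_covariates=["treatment", "age_decades"],
        severity_covariates=["treatment", "age_decades"],
        include_zi=False, re_components="",
    )
    log_sd, _ = re_covariance_to_unconstrained([1e-9] * 3, [0, 0, 0])
    params = ModelParameters(
        beta_B=[4.6, 0.5, 0.05], beta_W=[2.4, -0.1, 0.02],
        beta_S=[-1.2, 0.2, -0.1], beta_ZI=[0.0],
        shape_B=1.1, shape_W=0.6, re_log_sd=log_sd,
    )
    cfg = SimulationConfig(
        n_subjects=n_subjects, true_params=params, model=model,
        covariates=[CovariateSpec("treatment", "bernoulli", (0.5,)),
                    CovariateSpec("age_decades", "normal", (4.9, 1.3))],
        follow_up=330.0, dropout_rate=4e-4,
    )
    return simulate_dataset(cfg, seed=seed)[0], model


def degenerate_collapse(seed: int = 0, n_subjects: int = 400) -> dict:
    """With no random effects and no zero-inflation, the joint likelihood is
    the sum of three standard fits: a censored AFT on between-gaps, an AFT on
    durations, and a logistic regression on severity.

    Compares the joint MLE log-likelihood against the summed log-likelihoods
    of independent lifelines / statsmodels fits, and evaluates the joint
    likelihood at the external MLEs (an exact identity).
    """
    import statsmodels.api as sm
    from lifelines import LogNormalAFTFitter

    subjects, model = _collapse_scenario(seed, n_subjects)
    pk = pack_dataset(subjects, model)
    fr = fit(pk, model, compute_vcov=False)

    covs = ["treatment", "age_decades"]

    def frame(entries):
        return pd.DataFrame(entries)

    rows = []
    for s in subjects:
        base = {c: s.covariates[c] for c in covs}
        for g in s.between_gaps():
            rows.append(dict(T=g, E=1, **base))
        if s.final_gap > 0:
            rows.append(dict(T=s.final_gap, E=0, **base))
    aft_b = LogNormalAFTFitter().fit(frame(rows), "T", "E")
    rows = [dict(T=e.duration, E=1 - e.within_censored,
                 **{c: s.covariates[c] for c in covs})
            for s in subjects for e in s.episodes]
    aft_w = LogNormalAFTFitter().fit(frame(rows), "T", "E")
    y = np.array([e.severity for s in subjects for e in s.episodes], float)
    X = np.column_stack([np.ones(len(y))] + [
        [s.covariates[c] for s in subjects for _ in s.episodes] for c in covs])
    logit = sm.Logit(y, X).fit(disp=0)
    external = float(aft_b.log_likelihood_ + aft_w.log_likelihood_ + logit.llf)

    def aft_params(f):
        mu = [f.params_.loc[("mu_", "Intercept")]] + [
            f.params_.loc[("mu_", c)] for c in covs]
        return np.asarray(mu), float(np.exp(f.params_.loc[("sigma_", "Intercept")]))

    bB, sB = aft_params(aft_b)
    bW, sW = aft_params(aft_w)
    log_sd, _ = re_covariance_to_unconstrained([1e-9] * 3, [0, 0, 0])
    theirs = ModelParameters(beta_B=bB, beta_W=bW,
                             beta_S=np.asarray(logit.params), beta_ZI=[0.0],
                             shape_B=sB, shape_W=sW, re_log_sd=log_sd)
    at_external = float(subject_logliks(pk, theirs, make_quadrature(5)).sum())
    return {
        "joint_mle_loglik": fr.loglik,
        "external_sum_loglik": external,
        "joint_at_external_params": at_external,
        "abs_diff_maximized": abs(fr.loglik - external),
        "abs_diff_at_same_params": abs(at_external - external),
        "n_subjects": n_subjects,
    }


def family_selection_study(n_replicates: int = 5, n_subjects: int = 300,
                           seed: int = 0, truth_family: str = "lognormal") -> dict:
    """AIC-based family selection on data simulated from log-normal gaps.

    A reduced joint scenario (intercept + treatment, rate/duration random
    effects, intercept-only zero-inflation) keeps each of the four candidate
    fits quick; returns the per-replicate winner.
    """
    model = ModelConfig(
        rate_covariates=["treatment"], duration_covariates=["treatment"],
        include_severity=False, zi_covariates=[], re_components="BW",
        family_rate=truth_family, family_duration=truth_family,
    )
    log_sd, corr = re_covariance_to_unconstrained([0.8, 0.5, 1.0],
                                                  [0.4, 0.0, 0.0])
    params = ModelParameters(
        beta_B=[4.6, np.log(2.0)], beta_W=[2.4, -0.15], beta_S=[0.0],
        beta_ZI=[-0.8], shape_B=1.2, shape_W=0.62,
        re_log_sd=log_sd, re_corr_chol=corr,
    )
    cfg = SimulationConfig(
        n_subjects=n_subjects, true_params=params, model=model,
        covariates=[CovariateSpec("treatment", "bernoulli", (0.5,))],
        follow_up=[(347.0, 0.55), (224.0, 0.45)], dropout_rate=4e-4,
    )
    winners, tables = [], []
    for rep in range(n_replicates):
        subjects, _ = simulate_dataset(cfg, seed=seed + 500 * rep + 7)
        table, _ = select_family(subjects, model)
        winners.append(table.loc[0, "family"])
        tables.append(table)
    wins = sum(w == truth_family for w in winners)
    return {"winners": winners, "wins": wins, "n_replicates": n_replicates,
            "tables": tables, "n_subjects": n_subjects}


def cdf_closure(seed: int = 0, n_subjects: int = 1000) -> dict:
    """Observed-versus-fitted marginal-CDF closure on model-simulated data.

    Simulates the case-study-like scenario and compares the model-implied
    marginal CDF (at the generating parameters, i.e. the model the data were
    'fitted' by construction) against the pooled-gap Kaplan-Meier curve.
    The between-gap comparison uses the unconditional (susceptibility-
    weighted) curve because the pooled KM risk sets include never-event
    subjects.
    """
    cfg = default_case_study_config(n_subjects=n_subjects)
    subjects, _ = simulate_dataset(cfg, seed=seed)
    pk = pack_dataset(subjects, cfg.model)
    pooled = pk.n_episodes + int((pk.final_gap > 0).sum())
    return {
        "sup_between": cdf_sup_distance(pk, cfg.true_params, "between",
                                        zi_mode="unconditional"),
        "sup_within": cdf_sup_distance(pk, cfg.true_params, "within"),
        "n_pooled_between_gaps": pooled,
        "n_within_gaps": pk.n_episodes,
    }
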