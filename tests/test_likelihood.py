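"""Conditional and marginal likelihood: hand-computed oracles, Monte-Carlo
integration checks, and quadrature behavior."""

import numpy as np
import pytest
from scipy import stats
from scipy.special import expit

from rdsjoint.config import ModelConfig
from rdsjoint.likelihood import (
    conditional_loglik,
    gauss_hermite_log_expectation,
    make_quadrature,
    marginal_subject_loglik,
    mc_marginal_subject_loglik,
    pack_dataset,
    subject_logliks,
    total_loglik,
)
from rdsjoint.model_core import (
    ExacerbationEpisode,
    ModelParameters,
    RandomEffects,
    SubjectHistory,
    re_covariance_to_unconstrained,
)


def _params(**kw):
    base = dict(
        beta_B=[4.4, 0.7, 0.05, 0.08],
        beta_W=[2.3, -0.1, 0.02, 0.05],
        beta_S=[-1.4, 0.1, -0.2, 0.15],
        beta_ZI=[-0.7, 0.3, 0.0, -0.6],
        shape_B=1.2,
        shape_W=0.62,
    )
    base.update(kw)
    return ModelParameters(**base)


@pytest.fixture()
def full_config():
    covs = ["treatment", "age_decades", "female"]
    return ModelConfig(rate_covariates=covs, duration_covariates=covs,
                       severity_covariates=covs, zi_covariates=covs)


# ---------------------------------------------------------------------------
# conditional log-likelihood
# ---------------------------------------------------------------------------


def test_conditional_zero_event_subject_is_censored_survival_term():
    cfg = ModelConfig(family_rate="lognormal")
    params = ModelParameters(beta_B=[4.0], beta_W=[0.0], beta_S=[0.0],
                             beta_ZI=[0.0], shape_B=1.3)
    subj = SubjectHistory("a", follow_up=250.0, final_gap=250.0,
                          final_gap_censored=1)
    z = RandomEffects(z_B=0.4)
    got = conditional_loglik(subj, params, z, cfg)
    expected = stats.norm.logsf((np.log(250.0) - 4.0 - 0.4) / 1.3)
    assert got == pytest.approx(float(expected), abs=1e-12)


def test_conditional_single_episode_exponential_reference():
    """Unit-rate exponential gaps and p = 1/2 severity: -1 - 1 + log(1/2)."""
    cfg = ModelConfig(family_rate="exponential", family_duration="exponential")
    params = ModelParameters(beta_B=[0.0], beta_W=[0.0], beta_S=[0.0],
                             beta_ZI=[0.0])
    subj = SubjectHistory(
        "b", follow_up=2.0,
        episodes=[ExacerbationEpisode(1.0, 2.0, severity=1)],
        final_gap=0.0, final_gap_censored=1)
    got = conditional_loglik(subj, params, RandomEffects(), cfg)
    assert got == pytest.approx(-1.0 - 1.0 + np.log(0.5), abs=1e-12)


def test_conditional_matches_term_by_term_recomputation(toy_subject, full_config):
    """Independent recomputation with plain scipy.stats calls."""
    params = _params()
    z = RandomEffects(z_B=0.3, z_W=-0.2, z_S=0.5)
    x = np.array([1.0, 1.0, 5.0, 0.0])  # intercept, treatment, age, female
    got = conditional_loglik(toy_subject, params, z, full_config)

    expected = 0.0
    gaps = [30.0, 60.0]  # onsets 30, 100 with terminations 40
    durs = [10.0, 12.0]
    sevs = [1, 0]
    for j in range(2):
        xj = np.r_[x, j, min(j, 1)]  # n_prior, n_prior_severe (first was severe)
        etaB = xj[:4] @ params.beta_B + z.z_B
        etaW = xj[:4] @ params.beta_W + z.z_W
        etaS = xj[:4] @ params.beta_S + z.z_S
        expected += stats.norm.logpdf(np.log(gaps[j]), etaB, 1.2) - np.log(gaps[j])
        expected += stats.norm.logpdf(np.log(durs[j]), etaW, 0.62) - np.log(durs[j])
        p = expit(etaS)
        expected += np.log(p) if sevs[j] else np.log(1 - p)
    etaB = x @ params.beta_B + z.z_B
    expected += stats.norm.logsf((np.log(88.0) - etaB) / 1.2)
    assert got == pytest.approx(float(expected), abs=1e-10)


def test_episode_covariates_enter_the_linear_predictors(toy_subject):
    """With n_prior in the rate submodel, the second episode and the final
    censored gap see updated counts."""
    covs = ["treatment", "n_prior", "n_prior_severe"]
    cfg = ModelConfig(rate_covariates=covs)
    params = ModelParameters(beta_B=[4.0, 0.2, 0.3, -0.4], beta_W=[2.0],
                             beta_S=[0.0], beta_ZI=[0.0], shape_B=1.0,
                             shape_W=1.0)
    got = conditional_loglik(toy_subject, params, RandomEffects(), cfg)
    expected = 0.0
    for gap, n, ns in [(30.0, 0, 0), (60.0, 1, 1)]:
        eta = 4.0 + 0.2 + 0.3 * n - 0.4 * ns
        expected += stats.norm.logpdf(np.log(gap), eta, 1.0) - np.log(gap)
    for dur in (10.0, 12.0):
        expected += stats.norm.logpdf(np.log(dur), 2.0, 1.0) - np.log(dur)
    expected += 2 * np.log(0.5)  # severity at p = 1/2
    expected += stats.norm.logsf(np.log(88.0) - (4.0 + 0.2 + 0.3 * 2 - 0.4 * 1))
    assert got == pytest.approx(float(expected), abs=1e-10)


def test_batched_kernel_agrees_with_per_subject_loop(small_dataset, case_config):
    subjects = small_dataset[0][:40]
    cfg = case_config.model
    params = case_config.true_params
    pk = pack_dataset(subjects, cfg)
    rng = np.random.default_rng(5)
    for z in rng.normal(size=(3, 3)):
        re = RandomEffects(*z)
        batch = []
        from rdsjoint.likelihood import _Eval, _expand

        ev = _Eval(pk, params)
        zb = np.broadcast_to(z, (1, 3))[None]
        cond_ev = ev.event_cond(z[None, None, :])[:, 0]
        cond_zero = ev.zero_cond(np.array([[z[0]]]))[:, 0]
        loop_ev = [conditional_loglik(s, params, re, cfg)
                   for s in subjects if s.n_episodes]
        loop_zero = [conditional_loglik(s, params, re, cfg)
                     for s in subjects if not s.n_episodes]
        np.testing.assert_allclose(cond_ev, loop_ev, atol=1e-9)
        np.testing.assert_allclose(cond_zero, loop_zero, atol=1e-9)


def test_conditional_rejects_mismatched_coefficients(toy_subject, full_config):
    params = _params(beta_B=[4.4, 0.7])
    with pytest.raises(ValueError, match="rate"):
        conditional_loglik(toy_subject, params, RandomEffects(), full_config)


# ---------------------------------------------------------------------------
# quadrature mechanics
# ---------------------------------------------------------------------------


def test_weights_normalize_to_one():
    """E[1] = 1 for any rule and covariance."""
    Sigma = np.array([[1.0, 0.3], [0.3, 2.0]])
    for pts in (1, 5, 9):
        lg = gauss_hermite_log_expectation(lambda z: np.zeros(len(z)), Sigma, pts)
        assert lg == pytest.approx(0.0, abs=1e-12)


@pytest.mark.parametrize("pts, tol", [(5, 1e-3), (9, 1e-5), (15, 1e-8)])
def test_lognormal_mgf_closed_form(pts, tol):
    """E[exp(a z)] = exp(a^2 sigma^2 / 2) for z ~ N(0, sigma^2), approached
    as the fixed Gauss-Hermite rule is refined."""
    a, sigma = 0.8, 1.3
    lg = gauss_hermite_log_expectation(
        lambda z: a * z[:, 0], np.array([[sigma**2]]), pts)
    assert lg == pytest.approx(a**2 * sigma**2 / 2, abs=tol)


def test_single_point_adaptive_rule_is_laplace_at_zero_when_degenerate():
    """With a single node and point-mass random effects the marginal equals
    the conditional at z = 0."""
    cfg = ModelConfig(include_zi=False)
    log_sd, _ = re_covariance_to_unconstrained([1e-8, 1e-8, 1e-8], [0, 0, 0])
    params = ModelParameters(beta_B=[4.0], beta_W=[2.0], beta_S=[0.0],
                             beta_ZI=[0.0], shape_B=1.2, shape_W=0.6,
                             re_log_sd=log_sd)
    subj = SubjectHistory(
        "c", follow_up=300.0,
        episodes=[ExacerbationEpisode(80.0, 95.0, 1)],
        final_gap=205.0, final_gap_censored=1)
    got = marginal_subject_loglik(subj, params, make_quadrature(1, "fixed"), cfg)
    want = conditional_loglik(subj, params, RandomEffects(), cfg)
    assert got == pytest.approx(want, abs=1e-8)


def test_marginal_collapses_to_conditional_when_sigma_zero(small_dataset, case_config):
    cfg = case_config.model
    log_sd, _ = re_covariance_to_unconstrained([1e-9] * 3, [0, 0, 0])
    params = case_config.true_params.copy()
    params.re_log_sd = log_sd
    params.re_corr_chol = np.zeros(3)
    rule = make_quadrature(5, "adaptive")
    for subj in small_dataset[0][:10]:
        got = marginal_subject_loglik(subj, params, rule, cfg)
        cond = conditional_loglik(subj, params, RandomEffects(), cfg)
        pi = float(expit(np.r_[1.0, [subj.covariates[c] for c in cfg.zi_covariates]]
                         @ params.beta_ZI))
        if subj.n_episodes:
            want = np.log(1 - pi) + cond
        else:
            want = np.log(pi + (1 - pi) * np.exp(cond))
        assert got == pytest.approx(want, abs=1e-8)


def test_degenerate_nonsusceptible_subject_has_loglik_zero(case_config):
    """pi -> 1 makes a zero-event subject certain: log-likelihood -> 0."""
    cfg = case_config.model
    params = case_config.true_params.copy()
    params.beta_ZI = np.array([40.0, 0.0, 0.0, 0.0])
    subj = SubjectHistory("d", follow_up=300.0, final_gap=300.0,
                          final_gap_censored=1,
                          covariates={"treatment": 0.0, "age_decades": 5.0,
                                      "female": 1.0})
    got = marginal_subject_loglik(subj, params, make_quadrature(5), cfg)
    assert got == pytest.approx(0.0, abs=1e-12)


def test_zi_collapse_matches_no_zi_model(small_dataset, case_config):
    """ZI intercept -> -inf degenerates to the likelihood without the
    mixture component."""
    from dataclasses import replace

    cfg = case_config.model
    params = case_config.true_params.copy()
    params.beta_ZI = np.array([-60.0, 0.0, 0.0, 0.0])
    pk = pack_dataset(small_dataset[0], cfg)
    with_zi = subject_logliks(pk, params, make_quadrature(5))
    cfg_nozi = replace(cfg, include_zi=False)
    pk2 = pack_dataset(small_dataset[0], cfg_nozi)
    without = subject_logliks(pk2, params, make_quadrature(5))
    np.testing.assert_allclose(with_zi, without, atol=1e-8)


def test_quadrature_convergence_5_9_13(small_packed, case_config):
    """Adaptive GH converges: the 5->9 point change is small per subject and
    the 9->13 change is an order of magnitude smaller."""
    params = case_config.true_params
    ll = {p: subject_logliks(small_packed, params, make_quadrature(p, "adaptive"))
          for p in (5, 9, 13)}
    d59 = np.abs(ll[5] - ll[9])
    d913 = np.abs(ll[9] - ll[13])
    assert d59.max() < 1e-3
    assert d913.sum() < 0.1 * max(d59.sum(), 1e-12)


def test_total_loglik_additivity_and_order_invariance(small_dataset, case_config):
    cfg = case_config.model
    params = case_config.true_params
    subs = small_dataset[0][:20]
    rule = make_quadrature(5)
    single = total_loglik([subs[0]], params, rule, cfg)
    assert single == pytest.approx(
        marginal_subject_loglik(subs[0], params, rule, cfg))
    doubled = total_loglik([subs[0], subs[0]], params, rule, cfg)
    assert doubled == pytest.approx(2 * single, abs=1e-9)
    fwd = total_loglik(subs, params, rule, cfg)
    rev = total_loglik(subs[::-1], params, rule, cfg)
    assert fwd == pytest.approx(rev, abs=1e-9)


def test_marginal_matches_monte_carlo_oracle(small_dataset, case_config):
    """Quadrature vs 50k-draw MC on a handful of subjects (3 SE agreement);
    the full-size check lives in the acceptance suite."""
    cfg = case_config.model
    params = case_config.true_params
    rng = np.random.default_rng(99)
    rule = make_quadrature(5, "adaptive")
    subs = sorted(small_dataset[0], key=lambda s: s.n_episodes)
    picks = [subs[0], subs[len(subs) // 2], subs[-1]]
    for s in picks:
        mc, se = mc_marginal_subject_loglik(s, params, cfg, 50_000, rng)
        quad = marginal_subject_loglik(s, params, rule, cfg)
        assert abs(quad - mc) < 3 * se + 1e-4
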