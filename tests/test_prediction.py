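"""Empirical-Bayes prediction, marginal means, and observed-vs-fitted CDFs."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats
from scipy.special import expit

from rdsjoint.config import ModelConfig
from rdsjoint.likelihood import pack_dataset
from rdsjoint.model_core import (
    ExacerbationEpisode,
    ModelParameters,
    SubjectHistory,
    re_covariance_to_unconstrained,
)
from rdsjoint.prediction import (
    cdf_sup_distance,
    empirical_bayes,
    empirical_cdf_curve,
    marginal_cdf_curve,
    marginal_mean_gap,
    marginal_severity_prob,
    subject_predictions,
)
from rdsjoint.simulate import default_case_study_config, simulate_dataset


# ---------------------------------------------------------------------------
# empirical Bayes
# ---------------------------------------------------------------------------


def test_eb_shrinks_to_zero_with_degenerate_prior(small_dataset, case_config):
    params = case_config.true_params.copy()
    log_sd, _ = re_covariance_to_unconstrained([1e-4] * 3, [0, 0, 0])
    params.re_log_sd = log_sd
    params.re_corr_chol = np.zeros(3)
    eb = empirical_bayes(small_dataset[0][:30], params, case_config.model)
    assert np.nanmax(np.abs(eb.to_numpy())) < 1e-3


def test_eb_zero_event_subject_gets_only_rate_component(case_config):
    subj = SubjectHistory("z", follow_up=300.0, final_gap=300.0,
                          final_gap_censored=1,
                          covariates={"treatment": 0, "age_decades": 5,
                                      "female": 1})
    eb = empirical_bayes([subj], case_config.true_params, case_config.model)
    row = eb.iloc[0]
    assert np.isfinite(row.z_B)
    assert np.isnan(row.z_W) and np.isnan(row.z_S)
    # long censored gap -> evidence for a slower-than-average rate: z_B > 0
    assert row.z_B > 0


def test_eb_estimates_shrink_and_track_truth():
    cfg = default_case_study_config(n_subjects=500)
    subs, truth = simulate_dataset(cfg, seed=17)
    eb = empirical_bayes(subs, cfg.true_params, cfg.model)
    zt = truth["per_subject"]
    j = eb.join(zt[["z_B", "z_W", "z_S"]], rsuffix="_true").dropna()
    assert len(j) > 100
    for comp, sd in (("z_B", 0.8), ("z_W", 0.5), ("z_S", 1.5)):
        r = np.corrcoef(j[comp], j[f"{comp}_true"])[0, 1]
        assert r > 0.5, comp
        assert j[comp].var() < sd**2  # shrinkage
        # approximately centred at zero
        assert abs(j[comp].mean()) < 3 * sd / np.sqrt(len(j)) + 0.3


# ---------------------------------------------------------------------------
# marginal means
# ---------------------------------------------------------------------------


def test_marginal_mean_closed_forms(case_config):
    cfg = case_config.model
    params = case_config.true_params.copy()
    # degenerate: no residual spread, no random effect
    params.beta_B = np.array([np.log(100.0), 0.0, 0.0, 0.0])
    params.shape_B = 1e-9
    log_sd, _ = re_covariance_to_unconstrained([1e-9, 1e-9, 1e-9], [0, 0, 0])
    params.re_log_sd = log_sd
    x = np.array([1.0, 0.0, 0.0, 0.0])
    assert marginal_mean_gap(x, params, cfg, "between") == pytest.approx(100.0, rel=1e-6)
    # log-normal multiplier exp(sigma^2/2) * exp(sigma_z^2/2)
    params.shape_B = np.sqrt(0.5)
    log_sd, _ = re_covariance_to_unconstrained(
        [np.sqrt(0.5), 1e-9, 1e-9], [0, 0, 0])
    params.re_log_sd = log_sd
    assert marginal_mean_gap(x, params, cfg, "between") == pytest.approx(
        100.0 * np.exp(0.5), rel=1e-6)


def test_loglogistic_divergent_mean_marker():
    cfg = ModelConfig(family_rate="loglogistic")
    params = ModelParameters(beta_B=[3.0], beta_W=[2.0], beta_S=[0.0],
                             beta_ZI=[0.0], shape_B=1.1, shape_W=0.5)
    assert marginal_mean_gap([1.0], params, cfg, "between") == np.inf


def test_marginal_severity_prob_against_numerical_integral(case_config):
    params = case_config.true_params
    x = np.array([1.0, 1.0, 4.0, 1.0])
    got = marginal_severity_prob(x, params, case_config.model)
    a = float(x @ params.beta_S)
    want = stats.norm.expect(lambda z: expit(a + 1.5 * z), lb=-10, ub=10)
    assert got == pytest.approx(want, abs=1e-6)


def test_subject_predictions_frame(small_dataset, case_config):
    sp = subject_predictions(small_dataset[0][:25], case_config.true_params,
                             case_config.model)
    assert (sp.mean_between > 0).all()
    assert (sp.mean_within > 0).all()
    assert sp.severity_prob.between(0, 1).all()
    cond = subject_predictions(small_dataset[0][:25], case_config.true_params,
                               case_config.model, conditional=True)
    ev = cond.dropna()
    assert not np.allclose(ev.mean_between, sp.loc[ev.index].mean_between)


# ---------------------------------------------------------------------------
# CDF curves
# ---------------------------------------------------------------------------


def test_marginal_cdf_properties(small_packed, case_config):
    grid = np.linspace(0, 400, 60)
    for which in ("between", "within"):
        curve = marginal_cdf_curve(small_packed, case_config.true_params,
                                   which, grid)["cdf"].to_numpy()
        assert curve[0] == pytest.approx(0.0, abs=1e-12)
        assert np.all(np.diff(curve) >= -1e-12)
        assert curve[-1] <= 1.0


def test_marginal_cdf_single_row_no_re_matches_family_cdf():
    cfg = ModelConfig(include_zi=False, re_components="")
    params = ModelParameters(beta_B=[4.0], beta_W=[2.0], beta_S=[0.0],
                             beta_ZI=[0.0], shape_B=1.2, shape_W=0.6)
    subj = SubjectHistory("s", follow_up=300.0, final_gap=300.0,
                          final_gap_censored=1)
    grid = np.linspace(0, 600, 50)
    got = marginal_cdf_curve([subj], params, "between", grid, cfg)["cdf"]
    want = stats.lognorm.cdf(grid, s=1.2, scale=np.exp(4.0))
    np.testing.assert_allclose(got, want, atol=1e-10)


def test_empty_grid_raises(small_packed, case_config):
    with pytest.raises(ValueError, match="grid"):
        marginal_cdf_curve(small_packed, case_config.true_params, "between", [])


def test_km_reduces_to_ecdf_without_censoring():
    subs = [SubjectHistory(i, follow_up=100.0 + g,
                           episodes=[ExacerbationEpisode(g, g + 5.0, 0)],
                           final_gap=100.0, final_gap_censored=1)
            for i, g in enumerate([10.0, 20.0, 30.0, 40.0])]
    grid = np.array([4.0, 15.0, 25.0, 35.0, 45.0])
    curve = empirical_cdf_curve(subs, "within", grid, ModelConfig())
    # all durations equal 5: empirical step from 0 to 1 at t = 5
    np.testing.assert_allclose(curve["cdf"], [0.0, 1.0, 1.0, 1.0, 1.0])
    curve = empirical_cdf_curve(subs, "between", grid, ModelConfig())
    # events 10,20,30,40 with four censored final gaps at 100 in the risk
    # set: S = 7/8, 6/8, 5/8, 4/8 after successive events
    np.testing.assert_allclose(curve["cdf"], [0.0, 1 / 8, 2 / 8, 3 / 8, 4 / 8])


def test_km_hand_computed_with_censoring():
    """Five gaps {5, 8+, 12, 15+, 20}: hand Kaplan-Meier values."""
    subs = []
    # three observed between-gaps via episodes; censored entries via final gaps
    subs.append(SubjectHistory(1, follow_up=30.0,
                               episodes=[ExacerbationEpisode(5.0, 6.0, 0)],
                               final_gap=24.0, final_gap_censored=1))
    subs[0].episodes[0].within_censored = 0
    subs.append(SubjectHistory(2, follow_up=8.0, final_gap=8.0, final_gap_censored=1))
    subs.append(SubjectHistory(3, follow_up=30.0,
                               episodes=[ExacerbationEpisode(12.0, 13.0, 0)],
                               final_gap=17.0, final_gap_censored=1))
    subs.append(SubjectHistory(4, follow_up=15.0, final_gap=15.0, final_gap_censored=1))
    subs.append(SubjectHistory(5, follow_up=40.0,
                               episodes=[ExacerbationEpisode(20.0, 21.0, 0)],
                               final_gap=19.0, final_gap_censored=1))
    # pooled between-gaps: events {5, 12, 20}, censored {24, 8, 17, 15, 19}
    # risk sets: t=5: 8 -> S=7/8; t=12: 6 -> S=7/8*5/6; t=20: 2 -> S=...*1/2
    grid = np.array([5.0, 12.0, 20.0])
    got = empirical_cdf_curve(subs, "between", grid, ModelConfig())["cdf"]
    S = np.array([7 / 8, 7 / 8 * 5 / 6, 7 / 8 * 5 / 6 * 1 / 2])
    np.testing.assert_allclose(got, 1 - S, atol=1e-12)


def test_all_censored_curve_undefined_beyond_last_event():
    subs = [SubjectHistory(i, follow_up=50.0, final_gap=50.0, final_gap_censored=1)
            for i in range(4)]
    with pytest.raises(ValueError, match="censored|observed"):
        empirical_cdf_curve(subs, "between", np.array([10.0]), ModelConfig())


def test_first_gap_closure_is_tight():
    """For *first* between-gaps the KM comparison is exact: the model mixture
    (1 - pi) F + pi at infinity matches KM within a KS-style band."""
    from lifelines import KaplanMeierFitter

    from rdsjoint.prediction import _row_marginal_cdf
    from rdsjoint.model_core import BaselineFamily

    cfg = default_case_study_config(n_subjects=2000)
    subs, _ = simulate_dataset(cfg, seed=23)
    pk = pack_dataset(subs, cfg.model)
    params = cfg.true_params

    t1, e1 = [], []
    for s in subs:
        if s.n_episodes:
            t1.append(s.episodes[0].onset_time)
            e1.append(1)
        else:
            t1.append(s.final_gap)
            e1.append(0)
    kmf = KaplanMeierFitter().fit(np.asarray(t1), np.asarray(e1))
    grid = np.linspace(1.0, np.quantile(t1, 0.95), 80)
    km_cdf = 1.0 - kmf.survival_function_at_times(grid).to_numpy()

    # model: first-episode covariate rows have prior counts zero == final row
    # covariates of zero-event subjects; use the per-subject baseline row
    X = pk.Xb_final.copy()
    etas = X @ params.beta_B
    fam = BaselineFamily(cfg.model.family_rate, params.shape_B)
    F = _row_marginal_cdf(grid, etas, fam, params.re_sds[0])
    pi = expit(pk.X_zi @ params.beta_ZI)
    model_cdf = (F * (1.0 - pi)[None, :]).mean(axis=1)
    assert np.max(np.abs(model_cdf - km_cdf)) < 0.05


def test_pooled_cdf_sup_distance_moderate(small_packed, case_config):
    d = cdf_sup_distance(small_packed, case_config.true_params, "within")
    assert 0 <= d < 0.25  # pooled-gap comparison carries systematic slack
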