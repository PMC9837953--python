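"""Empirical-Bayes random-effect prediction, marginal predicted means, and
observed-versus-fitted marginal CDF curves.

The empirical-Bayes (EB) predictor of a subject's random effects is the mode
of the posterior of Z given the subject's data at the fitted parameters.  For
zero-event subjects only the rate component z_B is identified.  EB estimates
exhibit shrinkage: their sample variance is smaller than the random-effect
variance, most strongly for subjects with little data.

Marginal predicted means use the log-normal-type factorization
``E[exp(eta + z + eps)] = exp(x'beta) * E[exp(eps)] * E[exp(z)]`` with the
closed-form mean of exp(eps) for each family and ``E[exp(z)] =
exp(sigma_z^2 / 2)``.

The marginal CDF of a gap time, averaged over the realized covariate rows of
a dataset, is compared against the Kaplan–Meier estimate on the pooled gaps
(1 - KM, with censored final between-gaps entering as censored) as a visual /
sup-distance goodness-of-fit check.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import expit, gamma as gamma_fn, logsumexp

from .config import ModelConfig
from .likelihood import PackedData, pack_dataset, posterior_modes
from .model_core import (
    BaselineFamily,
    ModelParameters,
    RandomEffects,
    SubjectHistory,
    aft_log_cdf,
    build_re_covariance,
)

__all__ = [
    "empirical_bayes",
    "subject_predictions",
    "marginal_mean_gap",
    "marginal_severity_prob",
    "marginal_cdf_curve",
    "empirical_cdf_curve",
]


# ---------------------------------------------------------------------------
# empirical Bayes
# ---------------------------------------------------------------------------


def empirical_bayes(dataset, params: ModelParameters,
                    config: ModelConfig | None = None) -> pd.DataFrame:
    """Posterior-mode random effects for every subject.

    Returns a data frame indexed by subject id with columns z_B, z_W, z_S;
    components not identified for a subject (duration/severity effects of
    zero-event subjects; inactive components) are NaN.
    """
    pk = dataset if isinstance(dataset, PackedData) else pack_dataset(dataset, config)
    modes = posterior_modes(pk, params)
    return pd.DataFrame(modes, columns=["z_B", "z_W", "z_S"],
                        index=pd.Index(pk.subject_ids, name="subject_id"))


def empirical_bayes_subject(subject: SubjectHistory, params: ModelParameters,
                            config: ModelConfig) -> RandomEffects:
    """EB prediction for a single subject (NaN components where unidentified)."""
    row = empirical_bayes([subject], params, config).iloc[0]
    return RandomEffects(z_B=row.z_B, z_W=row.z_W, z_S=row.z_S)


# ---------------------------------------------------------------------------
# marginal means
# ---------------------------------------------------------------------------


def _mean_exp_eps(fam: BaselineFamily) -> float:
    """E[exp(eps)] for the AFT error law; +inf where the moment diverges."""
    s = fam.shape
    if fam.family == "lognormal":
        return float(np.exp(0.5 * s**2))
    if fam.family in ("weibull", "exponential"):
        return float(gamma_fn(1.0 + s))
    # loglogistic: finite only for shape < 1
    if s >= 1.0:
        return np.inf
    return float(np.pi * s / np.sin(np.pi * s))


def marginal_mean_gap(x_row, params: ModelParameters, config: ModelConfig,
                      which: str = "between", z: float | None = None) -> float:
    """Expected gap time (days) for one covariate row.

    With ``z=None`` the random effect is integrated out (fully marginal mean,
    multiplier exp(sigma_z^2/2)); passing a fixed ``z`` (e.g. an EB estimate)
    gives the subject-conditional mean.  Returns +inf when the family moment
    diverges (log-logistic with shape >= 1).
    """
    if which not in ("between", "within"):
        raise ValueError("which must be 'between' or 'within'")
    if which == "between":
        fam = BaselineFamily(config.family_rate, params.shape_B)
        eta = float(np.asarray(x_row) @ params.beta_B)
        comp = 0
    else:
        fam = BaselineFamily(config.family_duration, params.shape_W)
        eta = float(np.asarray(x_row) @ params.beta_W)
        comp = 1
    m_eps = _mean_exp_eps(fam)
    if not np.isfinite(m_eps):
        return np.inf
    if z is None:
        sigma_z = params.re_sds[comp] if comp in config.active_re else 0.0
        m_z = np.exp(0.5 * sigma_z**2)
    else:
        m_z = np.exp(z)
    return float(np.exp(eta) * m_eps * m_z)


def marginal_severity_prob(x_row, params: ModelParameters, config: ModelConfig,
                           z: float | None = None, gh_points: int = 41) -> float:
    """P(severe) for one covariate row, integrating z_S out by 1-D
    Gauss–Hermite quadrature (or conditioning on a supplied z)."""
    a = float(np.asarray(x_row) @ params.beta_S)
    if z is not None:
        return float(expit(a + z))
    sigma_z = params.re_sds[2] if 2 in config.active_re else 0.0
    if sigma_z == 0.0:
        return float(expit(a))
    u, w = np.polynomial.hermite.hermgauss(gh_points)
    return float((w / np.sqrt(np.pi)) @ expit(a + np.sqrt(2.0) * sigma_z * u))


def subject_predictions(dataset, params: ModelParameters,
                        config: ModelConfig | None = None,
                        conditional: bool = False) -> pd.DataFrame:
    """Per-subject EB random effects and predicted mean outcomes.

    Covariate rows are the subject's baseline rows (prior-event counts at 0).
    With ``conditional=True`` the means condition on the EB estimates (NaN
    where the EB component is unidentified); otherwise they are fully
    marginal over the random effects.
    """
    pk = dataset if isinstance(dataset, PackedData) else pack_dataset(dataset, config)
    cfg = pk.config
    eb = empirical_bayes(pk, params)
    rows = []
    # baseline design rows: first episode row where available, else final row
    subjects = {i: k for k, i in enumerate(pk.event_idx)}
    for i, sid in enumerate(pk.subject_ids):
        if i in subjects:
            k = pk.ep_starts[subjects[i]]
            xb, xw, xs = pk.Xb_ep[k], pk.Xw_ep[k], pk.Xs_ep[k]
        else:
            xb = pk.Xb_final[i]
            xw = np.r_[pk.Xb_final[i][:1], np.zeros(len(cfg.duration_covariates))]
            xs = np.r_[pk.Xb_final[i][:1], np.zeros(len(cfg.severity_covariates))]
        z = eb.loc[sid]
        zB, zW, zS = (z.z_B, z.z_W, z.z_S) if conditional else (None, None, None)
        rows.append({
            "subject_id": sid,
            "z_B": z.z_B, "z_W": z.z_W, "z_S": z.z_S,
            "mean_between": marginal_mean_gap(xb, params, cfg, "between", zB),
            "mean_within": marginal_mean_gap(xw, params, cfg, "within", zW)
            if cfg.include_duration else np.nan,
            "severity_prob": marginal_severity_prob(xs, params, cfg, zS)
            if cfg.include_severity else np.nan,
        })
    return pd.DataFrame(rows).set_index("subject_id")


# ---------------------------------------------------------------------------
# marginal and empirical CDF curves
# ---------------------------------------------------------------------------


def _row_marginal_cdf(t_grid, etas, fam, sigma_z, gh_points=41):
    """P(T <= t) for each (grid point, covariate row): z integrated by GH."""
    t_grid = np.asarray(t_grid, dtype=float)
    if sigma_z == 0.0:
        return np.exp(aft_log_cdf(t_grid[:, None], etas[None, :], fam))
    u, w = np.polynomial.hermite.hermgauss(gh_points)
    wn = w / np.sqrt(np.pi)
    z = np.sqrt(2.0) * sigma_z * u  # (Q,)
    # (T, R, Q) collapsed over Q
    lc = aft_log_cdf(t_grid[:, None, None], etas[None, :, None] + z[None, None, :], fam)
    return np.exp(logsumexp(lc + np.log(wn)[None, None, :], axis=-1))


def marginal_cdf_curve(dataset, params: ModelParameters, which: str = "between",
                       grid=None, config: ModelConfig | None = None,
                       zi_mode: str = "conditional") -> pd.DataFrame:
    """Model-implied marginal CDF of a gap time, averaged over the realized
    covariate rows of the dataset.

    For the between-gap ("rate") curve, `zi_mode` controls the zero-inflation
    weight: ``"conditional"`` (default) reports the gap distribution of
    susceptible subjects; ``"unconditional"`` multiplies each subject's CDF
    by its susceptibility probability 1 - pi_i, placing the non-susceptible
    mass at +infinity.
    """
    pk = dataset if isinstance(dataset, PackedData) else pack_dataset(dataset, config)
    cfg = pk.config
    if grid is None or len(np.atleast_1d(grid)) == 0:
        raise ValueError("a non-empty time grid is required")
    grid = np.asarray(grid, dtype=float)
    if which == "between":
        fam = BaselineFamily(cfg.family_rate, params.shape_B)
        X = np.vstack([pk.Xb_ep, pk.Xb_final]) if pk.n_episodes else pk.Xb_final
        etas = X @ params.beta_B
        sigma_z = params.re_sds[0] if 0 in cfg.active_re else 0.0
        weights = np.ones(len(etas))
        if cfg.include_zi and zi_mode == "unconditional":
            pi = expit(pk.X_zi @ params.beta_ZI)
            w_subj = 1.0 - pi
            weights = np.r_[
                np.ones(pk.n_episodes),  # observed gaps come from susceptibles
                w_subj,
            ] if pk.n_episodes else w_subj
        elif zi_mode not in ("conditional", "unconditional"):
            raise ValueError("zi_mode must be 'conditional' or 'unconditional'")
    elif which == "within":
        if not cfg.include_duration:
            raise ValueError("duration submodel disabled")
        fam = BaselineFamily(cfg.family_duration, params.shape_W)
        etas = pk.Xw_ep @ params.beta_W
        sigma_z = params.re_sds[1] if 1 in cfg.active_re else 0.0
        weights = np.ones(len(etas))
    else:
        raise ValueError("which must be 'between' or 'within'")
    F = _row_marginal_cdf(grid, etas, fam, sigma_z)  # (T, R)
    if which == "between" and cfg.include_zi and zi_mode == "unconditional":
        # susceptibility weight scales the subject's whole CDF for final rows;
        # event rows condition on having come from a susceptible subject
        Ff = F[:, pk.n_episodes:] * weights[pk.n_episodes:][None, :] \
            if pk.n_episodes else F * weights[None, :]
        Fe = F[:, :pk.n_episodes] if pk.n_episodes else np.zeros((len(grid), 0))
        curve = np.hstack([Fe, Ff]).mean(axis=1)
    else:
        curve = F.mean(axis=1)
    return pd.DataFrame({"time": grid, "cdf": curve})


def empirical_cdf_curve(dataset, which: str = "between", grid=None,
                        config: ModelConfig | None = None) -> pd.DataFrame:
    """Kaplan–Meier-based empirical CDF (1 - KM) of the pooled gap times.

    Between-gaps pool the completed gaps (events) and the positive censored
    final gaps; within-gaps pool the episode durations with their censoring
    flags.  Beyond the last observed event time the KM curve is undefined if
    the largest observation is censored; the returned frame flags that region.
    """
    from lifelines import KaplanMeierFitter

    pk = dataset if isinstance(dataset, PackedData) else pack_dataset(dataset, config)
    if grid is None or len(np.atleast_1d(grid)) == 0:
        raise ValueError("a non-empty time grid is required")
    grid = np.asarray(grid, dtype=float)
    if which == "between":
        pos = pk.final_gap > 0
        times = np.r_[pk.B, pk.final_gap[pos]]
        observed = np.r_[np.ones(pk.n_episodes), np.zeros(pos.sum())]
    elif which == "within":
        times = pk.W
        observed = 1.0 - pk.within_cens.astype(float)
    else:
        raise ValueError("which must be 'between' or 'within'")
    if len(times) == 0 or observed.sum() == 0:
        raise ValueError("no observed (uncensored) gap times to estimate from")
    kmf = KaplanMeierFitter()
    kmf.fit(times, event_observed=observed)
    surv = kmf.survival_function_at_times(grid).to_numpy()
    last_event = times[observed.astype(bool)].max()
    defined = grid <= max(last_event, times.max() if observed.all() else last_event)
    return pd.DataFrame({"time": grid, "cdf": 1.0 - surv, "defined": defined})


def cdf_sup_distance(dataset, params: ModelParameters, which: str = "between",
                     config: ModelConfig | None = None, n_grid: int = 200,
                     zi_mode: str = "conditional") -> float:
    """Sup-distance between the fitted marginal CDF and the KM empirical CDF
    over the span of observed gap times (the observed-vs-fitted visual check made
    quantitative)."""
    pk = dataset if isinstance(dataset, PackedData) else pack_dataset(dataset, config)
    times = pk.B if which == "between" else pk.W
    if len(times) == 0:
        raise ValueError("no gaps to compare")
    grid = np.linspace(0.0, np.quantile(times, 0.99), n_grid)
    fitted = marginal_cdf_curve(pk, params, which, grid, zi_mode=zi_mode)["cdf"]
    emp = empirical_cdf_curve(pk, which, grid)
    ok = emp["defined"].to_numpy()
    return float(np.max(np.abs(fitted.to_numpy()[ok] - emp["cdf"].to_numpy()[ok])))
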