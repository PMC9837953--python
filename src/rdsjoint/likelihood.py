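"""Joint-model log-likelihood: conditional on the random effects, and marginal
via (adaptive) Gauss–Hermite quadrature.

The marginal likelihood of one subject mixes a zero-inflation (cure) component
with the random-effect integral of the conditional likelihood::

    M = 0:   L_i = pi_i + (1 - pi_i) * E_Z[ L_i(Z) ]
    M >= 1:  L_i = (1 - pi_i) * E_Z[ L_i(Z) ]

where ``Z ~ MVN(0, Sigma_Z)`` over the active random-effect components.  For
zero-event subjects the conditional likelihood depends only on z_B (a censored
survival term), so the integral collapses to one dimension.  Conditional on Z
the submodel contributions factorize: an AFT density for each completed
between-gap, an AFT density (or survival term if within-censored) for each
duration, a Bernoulli-logit term for each severity mark, and a survival term
for the censored final between-gap.

Integration uses a tensor-product Gauss–Hermite rule.  In adaptive mode the
grid is recentred at the per-subject posterior mode of Z and rescaled by the
inverse Cholesky factor of the negative log-posterior Hessian; the conditional
log-likelihood is concave in Z with a *diagonal* Hessian (each term involves a
single component), so the mode search is a plain damped Newton iteration with
analytic derivatives.  All mixture/quadrature sums go through log-sum-exp.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import logsumexp

from .config import EPISODE_COVARIATES, ModelConfig
from .model_core import (
    BaselineFamily,
    ModelParameters,
    RandomEffects,
    SubjectHistory,
    aft_d2logS_deta2,
    aft_d2logf_deta2,
    aft_dlogS_deta,
    aft_dlogf_deta,
    aft_log_density,
    aft_log_survival,
    build_re_covariance,
    design_row,
)

__all__ = [
    "QuadratureRule",
    "make_quadrature",
    "PackedData",
    "pack_dataset",
    "conditional_loglik",
    "marginal_subject_loglik",
    "subject_logliks",
    "total_loglik",
    "mc_marginal_subject_loglik",
    "gauss_hermite_log_expectation",
]

_SQRT2 = np.sqrt(2.0)
_LOG_SQRT_PI = 0.5 * np.log(np.pi)


# ---------------------------------------------------------------------------
# quadrature rule
# ---------------------------------------------------------------------------


@dataclass
class QuadratureRule:
    """Tensor-product Gauss–Hermite rule (physicists' weight e^{-u^2})."""

    points_per_dim: int = 5
    mode: str = "adaptive"
    _grids: dict = field(default_factory=dict, repr=False)
    _mode_cache: dict = field(default_factory=dict, repr=False)

    def __post_init__(self):
        if self.points_per_dim < 1:
            raise ValueError("points_per_dim must be >= 1")
        if self.mode not in ("adaptive", "fixed"):
            raise ValueError("quadrature mode must be 'adaptive' or 'fixed'")

    def grid(self, d: int):
        """Nodes ``u`` (K, d), log-weights (K,) and |u|^2 (K,) for dimension d."""
        if d not in self._grids:
            x, w = np.polynomial.hermite.hermgauss(self.points_per_dim)
            nodes = np.stack(
                [g.ravel() for g in np.meshgrid(*([x] * d), indexing="ij")], axis=-1
            )
            lw1 = np.log(w)
            logw = np.stack(
                [g.ravel() for g in np.meshgrid(*([lw1] * d), indexing="ij")], axis=-1
            ).sum(axis=-1)
            self._grids[d] = (nodes, logw, (nodes**2).sum(axis=-1))
        return self._grids[d]


def make_quadrature(points_per_dim: int = 5, mode: str = "adaptive") -> QuadratureRule:
    return QuadratureRule(points_per_dim=points_per_dim, mode=mode)


def gauss_hermite_log_expectation(logg, Sigma, points: int = 5):
    """log E_Z[exp(logg(Z))] for Z ~ MVN(0, Sigma), fixed Sigma-scaled grid.

    `logg` maps an (K, d) array of points to (K,) log-integrand values.  Used
    as a small generic utility (weight normalization, moment-generating-
    function checks); the model likelihood uses the specialised batched path.
    """
    Sigma = np.atleast_2d(np.asarray(Sigma, dtype=float))
    d = Sigma.shape[0]
    rule = QuadratureRule(points_per_dim=points, mode="fixed")
    u, logw, _ = rule.grid(d)
    L = np.linalg.cholesky(Sigma)
    z = _SQRT2 * u @ L.T
    return logsumexp(logw - d * _LOG_SQRT_PI + np.asarray(logg(z), dtype=float))


# ---------------------------------------------------------------------------
# packed dataset
# ---------------------------------------------------------------------------


@dataclass
class PackedData:
    """Dataset flattened into arrays for vectorized likelihood evaluation.

    Episodes are stacked contiguously, grouped by subject, for subjects with
    at least one event ("event subjects"); zero-event subjects contribute only
    a censored final between-gap.
    """

    config: ModelConfig
    subject_ids: list
    M: np.ndarray            # (n,) episode counts
    event_idx: np.ndarray    # (ne,) subject indices with M >= 1
    zero_idx: np.ndarray     # (nz,) subject indices with M == 0
    ep_starts: np.ndarray    # (ne,) reduceat offsets into episode arrays
    ep_evt: np.ndarray       # (n_ep,) event-subject index per episode
    B: np.ndarray
    W: np.ndarray
    S: np.ndarray
    within_cens: np.ndarray
    Xb_ep: np.ndarray        # (n_ep, pB)
    Xw_ep: np.ndarray
    Xs_ep: np.ndarray
    final_gap: np.ndarray    # (n,)
    Xb_final: np.ndarray     # (n, pB)
    X_zi: np.ndarray         # (n, pZI)

    @property
    def n(self) -> int:
        return len(self.subject_ids)

    @property
    def n_episodes(self) -> int:
        return len(self.B)


def _submodel_rows(subject: SubjectHistory, names, counts) -> np.ndarray:
    """Design rows [1, x...] for the named columns, one per episode row."""
    base = design_row(subject.covariates, [n for n in names if n not in EPISODE_COVARIATES],
                      subject.subject_id)
    nrows = counts.shape[0]
    out = np.empty((nrows, 1 + len(names)))
    out[:, 0] = 1.0
    col = 1
    base_col = 1
    for n in names:
        if n == "n_prior":
            out[:, col] = counts[:, 0]
        elif n == "n_prior_severe":
            out[:, col] = counts[:, 1]
        else:
            out[:, col] = base[base_col]
            base_col += 1
        col += 1
    return out


def pack_dataset(dataset, config: ModelConfig) -> PackedData:
    """Validate and flatten a list of :class:`SubjectHistory`."""
    if len(dataset) == 0:
        raise ValueError("empty dataset")
    if not config.derive_episode_covariates:
        for names in (config.rate_covariates, config.duration_covariates,
                      config.severity_covariates):
            bad = [n for n in names if n in EPISODE_COVARIATES]
            if bad:
                raise ValueError(
                    f"episode covariates {bad} requested but "
                    "derive_episode_covariates is off"
                )

    ids, M = [], []
    ev_list, zero_list = [], []
    ep_starts, ep_evt = [], []
    B, W, S, wc = [], [], [], []
    Xb_ep, Xw_ep, Xs_ep = [], [], []
    final_gap, Xb_final, X_zi = [], [], []

    for i, subj in enumerate(dataset):
        subj.validate()
        ids.append(subj.subject_id)
        M.append(subj.n_episodes)
        counts = subj.episode_counts(include_final=True)  # (M+1, 2)
        rate_rows = _submodel_rows(subj, config.rate_covariates, counts)
        final_gap.append(subj.final_gap)
        Xb_final.append(rate_rows[-1])
        X_zi.append(design_row(subj.covariates, config.zi_covariates, subj.subject_id))
        if subj.n_episodes == 0:
            zero_list.append(i)
            continue
        e = len(ev_list)
        ev_list.append(i)
        ep_starts.append(len(B))
        gaps = subj.between_gaps()
        dur_rows = _submodel_rows(subj, config.duration_covariates, counts[:-1])
        sev_rows = _submodel_rows(subj, config.severity_covariates, counts[:-1])
        for j, ep in enumerate(subj.episodes):
            ep_evt.append(e)
            B.append(gaps[j])
            W.append(ep.duration)
            S.append(ep.severity)
            wc.append(ep.within_censored)
            Xb_ep.append(rate_rows[j])
            Xw_ep.append(dur_rows[j])
            Xs_ep.append(sev_rows[j])

    def arr(x, width=None):
        if len(x) == 0:
            return np.zeros((0, width)) if width else np.zeros(0)
        return np.asarray(x, dtype=float)

    return PackedData(
        config=config,
        subject_ids=ids,
        M=np.asarray(M, dtype=int),
        event_idx=np.asarray(ev_list, dtype=int),
        zero_idx=np.asarray(zero_list, dtype=int),
        ep_starts=np.asarray(ep_starts, dtype=int),
        ep_evt=np.asarray(ep_evt, dtype=int),
        B=arr(B), W=arr(W), S=arr(S), within_cens=np.asarray(wc, dtype=bool)
        if wc else np.zeros(0, dtype=bool),
        Xb_ep=arr(Xb_ep, 1 + len(config.rate_covariates)),
        Xw_ep=arr(Xw_ep, 1 + len(config.duration_covariates)),
        Xs_ep=arr(Xs_ep, 1 + len(config.severity_covariates)),
        final_gap=arr(final_gap),
        Xb_final=arr(Xb_final, 1 + len(config.rate_covariates)),
        X_zi=arr(X_zi, 1 + len(config.zi_covariates)),
    )


# ---------------------------------------------------------------------------
# evaluation context (per parameter value)
# ---------------------------------------------------------------------------


def _check_lengths(pk: PackedData, pr: ModelParameters):
    pairs = [
        ("rate", pk.Xb_final.shape[1], len(pr.beta_B)),
        ("duration", pk.Xw_ep.shape[1], len(pr.beta_W)) if pk.config.include_duration else None,
        ("severity", pk.Xs_ep.shape[1], len(pr.beta_S)) if pk.config.include_severity else None,
        ("zero-inflation", pk.X_zi.shape[1], len(pr.beta_ZI)) if pk.config.include_zi else None,
    ]
    for item in pairs:
        if item is None:
            continue
        name, ncol, nb = item
        if ncol != nb:
            raise ValueError(
                f"{name} submodel: design has {ncol} columns but coefficient "
                f"vector has length {nb}"
            )


class _Eval:
    """Per-parameter-value caches and batched conditional kernels."""

    def __init__(self, pk: PackedData, pr: ModelParameters):
        cfg = pk.config
        _check_lengths(pk, pr)
        self.pk, self.pr, self.cfg = pk, pr, cfg
        self.famB = BaselineFamily(cfg.family_rate, pr.shape_B)
        self.famW = BaselineFamily(cfg.family_duration, pr.shape_W)
        self.etaB_ep = pk.Xb_ep @ pr.beta_B if pk.n_episodes else np.zeros(0)
        self.etaW_ep = pk.Xw_ep @ pr.beta_W if pk.n_episodes and cfg.include_duration else None
        self.etaS_ep = pk.Xs_ep @ pr.beta_S if pk.n_episodes and cfg.include_severity else None
        self.etaB_final = pk.Xb_final @ pr.beta_B
        if cfg.include_zi:
            a = pk.X_zi @ pr.beta_ZI
            self.log_pi = -np.logaddexp(0.0, -a)
            self.log1m_pi = -np.logaddexp(0.0, a)
        self.active = cfg.active_re
        d = len(self.active)
        if d:
            Sigma, _, _ = build_re_covariance(pr.re_log_sd, pr.re_corr_chol)
            self.Sigma = Sigma[np.ix_(self.active, self.active)]
            self.L = np.linalg.cholesky(self.Sigma)
            self.Linv = np.linalg.inv(self.L)
            self.Prec = self.Linv.T @ self.Linv
            self.logdet_half = np.log(np.diag(self.L)).sum()
        # final-gap masks on the event/zero groups
        self.fin_ev = pk.final_gap[pk.event_idx]
        self.fin_ev_pos = self.fin_ev > 0
        self.fin_zero = pk.final_gap[pk.zero_idx]
        self.fin_zero_pos = self.fin_zero > 0

    # -- full (3-component) z kernels ------------------------------------

    def event_cond(self, z):
        """Conditional log-likelihood of event subjects at z-batch.

        `z` has shape (K, 3) (shared nodes) or (ne, K, 3); returns (ne, K).
        """
        pk, cfg = self.pk, self.cfg
        ne = len(pk.event_idx)
        z = np.broadcast_to(z, (ne,) + z.shape[-2:])
        ze = z[pk.ep_evt]  # (n_ep, K, 3)
        ll = aft_log_density(pk.B[:, None], self.etaB_ep[:, None] + ze[:, :, 0], self.famB)
        if cfg.include_duration:
            etaW = self.etaW_ep[:, None] + ze[:, :, 1]
            ld = aft_log_density(pk.W[:, None], etaW, self.famW)
            if pk.within_cens.any():
                c = pk.within_cens
                ld[c] = aft_log_survival(pk.W[c, None], etaW[c], self.famW)
            ll = ll + ld
        if cfg.include_severity:
            a = self.etaS_ep[:, None] + ze[:, :, 2]
            ll = ll - np.logaddexp(0.0, (1.0 - 2.0 * pk.S)[:, None] * a)
        out = np.add.reduceat(ll, pk.ep_starts, axis=0)
        if self.fin_ev_pos.any():
            m = self.fin_ev_pos
            out[m] += aft_log_survival(
                self.fin_ev[m, None], self.etaB_final[pk.event_idx][m, None] + z[m][:, :, 0],
                self.famB,
            )
        return out

    def event_grad_hess(self, z):
        """Gradient (ne, 3) and diagonal Hessian (ne, 3) of the conditional
        log-likelihood of event subjects with respect to (z_B, z_W, z_S)."""
        pk, cfg = self.pk, self.cfg
        ne = len(pk.event_idx)
        z = np.broadcast_to(z, (ne, 3))
        ze = z[pk.ep_evt]
        g = np.zeros((ne, 3))
        h = np.zeros((ne, 3))
        etaB = self.etaB_ep + ze[:, 0]
        g[:, 0] = np.add.reduceat(aft_dlogf_deta(pk.B, etaB, self.famB), pk.ep_starts)
        h[:, 0] = np.add.reduceat(aft_d2logf_deta2(pk.B, etaB, self.famB), pk.ep_starts)
        if self.fin_ev_pos.any():
            m = self.fin_ev_pos
            etaF = self.etaB_final[pk.event_idx][m] + z[m][:, 0]
            g[m, 0] += aft_dlogS_deta(self.fin_ev[m], etaF, self.famB)
            h[m, 0] += aft_d2logS_deta2(self.fin_ev[m], etaF, self.famB)
        if cfg.include_duration:
            etaW = self.etaW_ep + ze[:, 1]
            gd = aft_dlogf_deta(pk.W, etaW, self.famW)
            hd = aft_d2logf_deta2(pk.W, etaW, self.famW)
            if pk.within_cens.any():
                c = pk.within_cens
                gd[c] = aft_dlogS_deta(pk.W[c], etaW[c], self.famW)
                hd[c] = aft_d2logS_deta2(pk.W[c], etaW[c], self.famW)
            g[:, 1] = np.add.reduceat(gd, pk.ep_starts)
            h[:, 1] = np.add.reduceat(hd, pk.ep_starts)
        if cfg.include_severity:
            from scipy.special import expit

            p = expit(self.etaS_ep + ze[:, 2])
            g[:, 2] = np.add.reduceat(pk.S - p, pk.ep_starts)
            h[:, 2] = np.add.reduceat(-p * (1.0 - p), pk.ep_starts)
        return g, h

    def zero_cond(self, zB):
        """Conditional log-likelihood of zero-event subjects at z_B batch
        (nz, K) or (K,); returns (nz, K)."""
        nz = len(self.pk.zero_idx)
        zB = np.broadcast_to(zB, (nz,) + zB.shape[-1:])
        out = np.zeros_like(zB, dtype=float)
        if self.fin_zero_pos.any():
            m = self.fin_zero_pos
            out[m] = aft_log_survival(
                self.fin_zero[m, None],
                self.etaB_final[self.pk.zero_idx][m, None] + zB[m],
                self.famB,
            )
        return out

    def zero_grad_hess(self, zB):
        nz = len(self.pk.zero_idx)
        zB = np.broadcast_to(zB, (nz,))
        g = np.zeros(nz)
        h = np.zeros(nz)
        m = self.fin_zero_pos
        if m.any():
            eta = self.etaB_final[self.pk.zero_idx][m] + zB[m]
            g[m] = aft_dlogS_deta(self.fin_zero[m], eta, self.famB)
            h[m] = aft_d2logS_deta2(self.fin_zero[m], eta, self.famB)
        return g[:, None], h[:, None]


# ---------------------------------------------------------------------------
# posterior modes (shared by AGH integration and empirical-Bayes prediction)
# ---------------------------------------------------------------------------


def _newton_modes(cond_fn, grad_hess_fn, Prec, n_group, d, start=None,
                  tol=1e-9, max_iter=60):
    """Vectorized damped Newton ascent of h(z) = cond(z) - z'Prec z / 2.

    cond_fn maps (g, 1, d) -> (g, 1); grad_hess_fn maps (g, d) -> (grad,
    diag-hess) of the conditional part.  Returns (modes, neg_hess) where
    neg_hess (g, d, d) = Prec - diag(hess) is the negative Hessian of h at the
    mode (positive definite by concavity).
    """
    z = np.zeros((n_group, d)) if start is None else start.copy()

    def h_val(zz):
        c = cond_fn(zz[:, None, :])[:, 0]
        return c - 0.5 * np.einsum("gi,ij,gj->g", zz, Prec, zz)

    hv = h_val(z)
    for _ in range(max_iter):
        g_c, h_c = grad_hess_fn(z)
        grad = g_c - z @ Prec
        if np.max(np.abs(grad), initial=0.0) < tol:
            break
        H = np.broadcast_to(Prec, (n_group, d, d)).copy()
        idx = np.arange(d)
        H[:, idx, idx] -= h_c
        step = np.linalg.solve(H, grad[..., None])[..., 0]
        alpha = np.ones(n_group)
        for _ in range(30):
            z_try = z + alpha[:, None] * step
            hv_try = h_val(z_try)
            bad = hv_try < hv - 1e-12
            if not bad.any():
                break
            alpha[bad] *= 0.5
        z = z + alpha[:, None] * step
        hv = h_val(z)
    g_c, h_c = grad_hess_fn(z)
    H = np.broadcast_to(Prec, (n_group, d, d)).copy()
    idx = np.arange(d)
    H[:, idx, idx] -= h_c
    return z, H


def _integrate_group(cond_fn, grad_hess_fn, Sigma, n_group, rule: QuadratureRule,
                     cache_key=None):
    """log E_Z[exp(cond(Z))], Z ~ MVN(0, Sigma), batched over a subject group.

    cond_fn maps a (g, K, d) z-batch to (g, K) conditional log-likelihoods.
    """
    d = Sigma.shape[0]
    u, logw, usq = rule.grid(d)
    L = np.linalg.cholesky(Sigma)
    if rule.mode == "fixed":
        z = _SQRT2 * u @ L.T  # (K, d)
        return logsumexp(logw - d * _LOG_SQRT_PI + cond_fn(z[None]), axis=-1)

    Prec = np.linalg.inv(Sigma)
    start = None
    if cache_key is not None:
        start = rule._mode_cache.get(cache_key)
        if start is not None and start.shape != (n_group, d):
            start = None
    modes, Hneg = _newton_modes(cond_fn, grad_hess_fn, Prec, n_group, d, start=start)
    if cache_key is not None:
        rule._mode_cache[cache_key] = modes
    try:
        C = np.linalg.cholesky(Hneg)
    except np.linalg.LinAlgError:
        # fall back to the fixed Sigma-scaled grid for the whole group
        z = _SQRT2 * u @ L.T
        return logsumexp(logw - d * _LOG_SQRT_PI + cond_fn(z[None]), axis=-1)
    Cinv = np.linalg.inv(C)
    # z = mode + sqrt(2) * C^{-T} u  for each subject
    z = modes[:, None, :] + _SQRT2 * np.einsum("gji,kj->gki", Cinv, u)
    logdetC = np.log(np.einsum("gii->gi", C)).sum(axis=-1)
    logphi = (
        -0.5 * d * np.log(2 * np.pi)
        - np.log(np.diag(L)).sum()
        - 0.5 * np.einsum("gki,ij,gkj->gk", z, Prec, z)
    )
    lse = logsumexp(logw[None, :] + usq[None, :] + cond_fn(z) + logphi, axis=-1)
    return 0.5 * d * np.log(2.0) - logdetC + lse


def posterior_modes(pk: PackedData, params: ModelParameters):
    """Posterior modes of the random effects given each subject's data.

    Returns an (n, 3) array; entries for components that are not identified
    for a subject (duration/severity effects of zero-event subjects, inactive
    components) are NaN.  Zero-event subjects get only a z_B mode.
    """
    ev = _Eval(pk, params)
    out = np.full((pk.n, 3), np.nan)
    act = list(ev.active)
    if not act:
        return out
    d = len(act)
    if len(pk.event_idx):
        modes, _ = _newton_modes(
            lambda z: ev.event_cond(_expand(z, act)),
            lambda z: _restrict(ev.event_grad_hess(_expand(z, act)), act),
            np.linalg.inv(ev.Sigma), len(pk.event_idx), d,
        )
        for k, a in enumerate(act):
            out[pk.event_idx, a] = modes[:, k]
    if len(pk.zero_idx) and 0 in act:
        s2 = ev.Sigma[act.index(0), act.index(0)]
        modes, _ = _newton_modes(
            lambda z: ev.zero_cond(z[:, :, 0]),
            lambda z: ev.zero_grad_hess(z[:, 0]),
            np.asarray([[1.0 / s2]]), len(pk.zero_idx), 1,
        )
        out[pk.zero_idx, 0] = modes[:, 0]
    return out


def _expand(z_act, active):
    """(g, K, d_active) -> (g, K, 3) with zeros in inactive components."""
    full = np.zeros(z_act.shape[:-1] + (3,))
    for k, a in enumerate(active):
        full[..., a] = z_act[..., k]
    return full


def _restrict(gh, active):
    g, h = gh
    return g[:, active], h[:, active]


# ---------------------------------------------------------------------------
# marginal log-likelihood
# ---------------------------------------------------------------------------


def subject_logliks(pk: PackedData, params: ModelParameters,
                    rule: QuadratureRule | None = None) -> np.ndarray:
    """Marginal log-likelihood contribution of every subject, in input order."""
    if rule is None:
        rule = make_quadrature(pk.config.quad_points, pk.config.quad_mode)
    ev = _Eval(pk, params)
    cfg = pk.config
    act = list(ev.active)
    out = np.empty(pk.n)

    ne, nz = len(pk.event_idx), len(pk.zero_idx)
    if ne:
        if act:
            logE = _integrate_group(
                lambda z: ev.event_cond(_expand(z, act)),
                lambda z: _restrict(ev.event_grad_hess(_expand(z, act)), act),
                ev.Sigma, ne, rule, cache_key=(id(pk), "event"),
            )
        else:
            logE = ev.event_cond(np.zeros((1, 3)))[:, 0]
        if cfg.include_zi:
            logE = logE + ev.log1m_pi[pk.event_idx]
        out[pk.event_idx] = logE
    if nz:
        if 0 in act:
            s2 = ev.Sigma[act.index(0), act.index(0)]
            logE = _integrate_group(
                lambda z: ev.zero_cond(z[:, :, 0]),
                lambda z: ev.zero_grad_hess(z[:, 0]),
                np.asarray([[s2]]), nz, rule, cache_key=(id(pk), "zero"),
            )
        else:
            logE = ev.zero_cond(np.zeros(1))[:, 0]
        if cfg.include_zi:
            logE = np.logaddexp(ev.log_pi[pk.zero_idx],
                                ev.log1m_pi[pk.zero_idx] + logE)
        out[pk.zero_idx] = logE

    if not np.all(np.isfinite(out)):
        bad = [pk.subject_ids[i] for i in np.nonzero(~np.isfinite(out))[0][:5]]
        raise FloatingPointError(
            f"non-finite marginal log-likelihood for subject(s) {bad}"
        )
    return out


def total_loglik(dataset, params: ModelParameters,
                 quad: QuadratureRule | None = None,
                 config: ModelConfig | None = None) -> float:
    """Total marginal log-likelihood.  `dataset` may be a list of
    SubjectHistory (requires `config`) or an already-packed dataset."""
    pk = dataset if isinstance(dataset, PackedData) else pack_dataset(dataset, config)
    return float(subject_logliks(pk, params, quad).sum())


def marginal_subject_loglik(subject: SubjectHistory, params: ModelParameters,
                            quad: QuadratureRule | None = None,
                            config: ModelConfig | None = None) -> float:
    """Marginal log-likelihood of a single subject."""
    if config is None:
        raise ValueError("config is required")
    pk = pack_dataset([subject], config)
    return float(subject_logliks(pk, params, quad)[0])


# ---------------------------------------------------------------------------
# reference implementations / oracles
# ---------------------------------------------------------------------------


def conditional_loglik(subject: SubjectHistory, params: ModelParameters,
                       z: RandomEffects, config: ModelConfig) -> float:
    """Conditional (on the random effects) log-likelihood of one subject.

    Plain per-episode loop; the batched kernels used for fitting are checked
    against this in the test-suite.
    """
    subject.validate()
    pk = pack_dataset([subject], config)
    _check_lengths(pk, params)
    famB = BaselineFamily(config.family_rate, params.shape_B)
    famW = BaselineFamily(config.family_duration, params.shape_W)
    counts = subject.episode_counts(include_final=True)
    rate_rows = _submodel_rows(subject, config.rate_covariates, counts)
    dur_rows = _submodel_rows(subject, config.duration_covariates, counts[:-1])
    sev_rows = _submodel_rows(subject, config.severity_covariates, counts[:-1])
    gaps = subject.between_gaps()
    ll = 0.0
    for j, ep in enumerate(subject.episodes):
        ll += float(aft_log_density(gaps[j], rate_rows[j] @ params.beta_B + z.z_B, famB))
        if config.include_duration:
            etaW = dur_rows[j] @ params.beta_W + z.z_W
            if ep.within_censored:
                ll += float(aft_log_survival(ep.duration, etaW, famW))
            else:
                ll += float(aft_log_density(ep.duration, etaW, famW))
        if config.include_severity:
            a = sev_rows[j] @ params.beta_S + z.z_S
            ll += float(-np.logaddexp(0.0, (1.0 - 2.0 * ep.severity) * a))
    if subject.final_gap_censored and subject.final_gap > 0:
        ll += float(aft_log_survival(
            subject.final_gap, rate_rows[-1] @ params.beta_B + z.z_B, famB))
    return ll


def mc_marginal_subject_loglik(subject: SubjectHistory, params: ModelParameters,
                               config: ModelConfig, n_draws: int = 200_000,
                               rng=None):
    """Monte-Carlo estimate of the marginal subject log-likelihood.

    Independent integration oracle for the quadrature path.  Returns
    ``(loglik, standard_error)`` where the SE is the delta-method SE of the
    log value.
    """
    rng = np.random.default_rng(rng)
    pk = pack_dataset([subject], config)
    ev = _Eval(pk, params)
    act = list(ev.active)
    d = len(act)
    if d:
        z_act = rng.multivariate_normal(np.zeros(d), ev.Sigma, size=n_draws)
    else:
        z_act = np.zeros((n_draws, 0))
    z_full = _expand(z_act[None], act)[0] if d else np.zeros((n_draws, 3))
    if subject.n_episodes:
        cond = ev.event_cond(z_full[None])[0]
    else:
        cond = ev.zero_cond(z_full[None, :, 0])[0]
    amax = cond.max()
    e = np.exp(cond - amax)
    Ehat = e.mean()
    se_E = e.std(ddof=1) / np.sqrt(n_draws)
    logE = amax + np.log(Ehat)
    if not config.include_zi:
        return logE, se_E / Ehat
    if subject.n_episodes:
        return logE + float(ev.log1m_pi[0]), se_E / Ehat
    pi = np.exp(ev.log_pi[0])
    L = pi + (1 - pi) * np.exp(logE)
    se = (1 - pi) * se_E * np.exp(amax) / L
    return float(np.log(L)), float(se)
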