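"""Distributional primitives for the joint rate–duration–severity (RDS) model.

The joint model describes recurrent disease exacerbations as an alternating
two-state process.  Each patient moves between an exacerbation-free ("healthy")
state and an exacerbation ("sick") state; the sojourn times are the
between-exacerbation gap times ``B`` (governing the event *rate*) and the
within-exacerbation gap times ``W`` (the event *duration*).  Each completed
exacerbation carries a binary *severity* mark ``S``.

Both gap-time submodels are accelerated failure time (AFT) models with an
additive subject-level random effect on the log-time scale::

    log T = x' beta + z + eps,    eps ~ family-specific error law

so ``exp(beta_k)`` multiplies the expected time to event (the "AFT factor").
Severity follows a logistic model with its own random effect, and an optional
zero-inflation (cure-fraction) component models a latent non-susceptible class
from baseline covariates only.  The three random effects are jointly normal
with an unstructured 3x3 covariance, parameterized here unconstrained via log
standard deviations and a correlation-Cholesky transform.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import special
from scipy.stats import norm

__all__ = [
    "FAMILIES",
    "BaselineFamily",
    "ExacerbationEpisode",
    "SubjectHistory",
    "RandomEffects",
    "ModelParameters",
    "linear_predictor",
    "aft_log_density",
    "aft_log_survival",
    "aft_hazard",
    "severity_prob",
    "nonsusceptible_prob",
    "build_re_covariance",
    "re_covariance_to_unconstrained",
]

FAMILIES = ("exponential", "weibull", "lognormal", "loglogistic")

RE_COMPONENTS = ("B", "W", "S")
# order of the correlation parameters: (B,W), (B,S), (W,S)
RE_PAIRS = ((0, 1), (0, 2), (1, 2))


# ---------------------------------------------------------------------------
# baseline families
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class BaselineFamily:
    """An AFT error law: ``log T = eta + eps`` with scale parameter `shape`.

    Parameterization (standard AFT conventions):

    * ``lognormal``:   eps ~ Normal(0, shape^2)
    * ``loglogistic``: eps ~ Logistic(0, shape)
    * ``weibull``:     exp(eps) ~ Weibull(shape parameter 1/shape, unit scale)
      i.e. eps is a minimum-extreme-value error with scale `shape`
    * ``exponential``: Weibull with shape ≡ 1 (no free shape parameter)
    """

    family: str
    shape: float = 1.0

    def __post_init__(self) -> None:
        if self.family not in FAMILIES:
            raise ValueError(
                f"unknown baseline family {self.family!r}; expected one of {FAMILIES}"
            )
        if self.family == "exponential":
            object.__setattr__(self, "shape", 1.0)
        if not np.isfinite(self.shape) or self.shape <= 0:
            raise ValueError(f"baseline shape must be positive, got {self.shape}")

    @property
    def has_free_shape(self) -> bool:
        return self.family != "exponential"


def _std_resid(t, eta, fam: BaselineFamily):
    """Standardized log-time residual s = (log t - eta) / sigma."""
    return (np.log(t) - eta) / fam.shape


def aft_log_density(t, eta, family: BaselineFamily):
    """log f(t) of the gap time under ``log T = eta + eps``.

    Vectorized over `t` and `eta` (broadcasting).  Requires t > 0.
    """
    t = np.asarray(t, dtype=float)
    eta = np.asarray(eta, dtype=float)
    if np.any(t <= 0):
        raise ValueError("aft_log_density requires strictly positive gap times")
    if not np.all(np.isfinite(eta)):
        raise ValueError("aft_log_density requires finite linear predictor eta")
    s = _std_resid(t, eta, family)
    sigma = family.shape
    base = -np.log(t) - np.log(sigma)
    if family.family in ("weibull", "exponential"):
        with np.errstate(over="ignore"):
            return base + s - np.exp(s)
    if family.family == "lognormal":
        return base - 0.5 * s**2 - 0.5 * np.log(2.0 * np.pi)
    # loglogistic: logistic density on the log scale
    return base + s - 2.0 * np.logaddexp(0.0, s)


def aft_log_survival(t, eta, family: BaselineFamily):
    """log S(t); S(0) = 1, non-increasing in t.  Requires t >= 0."""
    t = np.asarray(t, dtype=float)
    eta = np.asarray(eta, dtype=float)
    if np.any(t < 0):
        raise ValueError("aft_log_survival requires non-negative gap times")
    if not np.all(np.isfinite(eta)):
        raise ValueError("aft_log_survival requires finite linear predictor eta")
    with np.errstate(divide="ignore"):  # log(0) -> -inf gives S(0)=1 in every family
        s = _std_resid(t, eta, family)
    if family.family in ("weibull", "exponential"):
        with np.errstate(over="ignore"):
            return -np.exp(s)
    if family.family == "lognormal":
        return norm.logsf(s)
    return -np.logaddexp(0.0, s)


def aft_hazard(t, eta, family: BaselineFamily):
    """Hazard h(t) = f(t) / S(t) of the gap time."""
    return np.exp(aft_log_density(t, eta, family) - aft_log_survival(t, eta, family))


def aft_dlogf_deta(t, eta, family: BaselineFamily):
    """d log f / d eta — used by the Newton mode search for the random effects."""
    s = _std_resid(np.asarray(t, float), np.asarray(eta, float), family)
    sigma = family.shape
    if family.family in ("weibull", "exponential"):
        with np.errstate(over="ignore"):
            return (np.exp(s) - 1.0) / sigma
    if family.family == "lognormal":
        return s / sigma
    return (2.0 * special.expit(s) - 1.0) / sigma


def aft_dlogS_deta(t, eta, family: BaselineFamily):
    """d log S / d eta (zero at t = 0)."""
    t = np.asarray(t, float)
    with np.errstate(divide="ignore"):
        s = _std_resid(t, np.asarray(eta, float), family)
    sigma = family.shape
    if family.family in ("weibull", "exponential"):
        with np.errstate(over="ignore"):
            return np.exp(s) / sigma
    if family.family == "lognormal":
        # phi(s) / Phi(-s) / sigma, computed on the log scale for tail stability
        out = np.exp(norm.logpdf(s) - norm.logsf(s)) / sigma
        return np.where(np.isneginf(s), 0.0, out)
    return special.expit(s) / sigma


def aft_d2logf_deta2(t, eta, family: BaselineFamily):
    """d^2 log f / d eta^2 (always <= 0: log-concavity in eta)."""
    s = _std_resid(np.asarray(t, float), np.asarray(eta, float), family)
    sig2 = family.shape**2
    if family.family in ("weibull", "exponential"):
        with np.errstate(over="ignore"):
            return -np.exp(s) / sig2
    if family.family == "lognormal":
        return -np.ones_like(s) / sig2
    p = special.expit(s)
    return -2.0 * p * (1.0 - p) / sig2


def aft_d2logS_deta2(t, eta, family: BaselineFamily):
    """d^2 log S / d eta^2 (<= 0; zero at t = 0)."""
    t = np.asarray(t, float)
    with np.errstate(divide="ignore"):
        s = _std_resid(t, np.asarray(eta, float), family)
    sig2 = family.shape**2
    if family.family in ("weibull", "exponential"):
        with np.errstate(over="ignore"):
            return -np.exp(s) / sig2
    if family.family == "lognormal":
        r = np.exp(norm.logpdf(s) - norm.logsf(s))  # normal hazard, r > s
        out = -r * (r - s) / sig2
        return np.where(np.isneginf(s), 0.0, out)
    p = special.expit(s)
    return -p * (1.0 - p) / sig2


def aft_eps_ppf(u, family: BaselineFamily):
    """Quantile of the AFT error eps — inverse-CDF sampling on the log scale."""
    u = np.asarray(u, dtype=float)
    sigma = family.shape
    if family.family in ("weibull", "exponential"):
        return sigma * np.log(-np.log1p(-u))
    if family.family == "lognormal":
        return sigma * norm.ppf(u)
    return sigma * (np.log(u) - np.log1p(-u))


def aft_log_cdf(t, eta, family: BaselineFamily):
    """log F(t) = log(1 - S(t))."""
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise ValueError("aft_log_cdf requires non-negative gap times")
    with np.errstate(divide="ignore"):
        s = _std_resid(t, np.asarray(eta, float), family)
    if family.family in ("weibull", "exponential"):
        # 1 - exp(-e^s)
        with np.errstate(over="ignore"):
            return np.log(-np.expm1(-np.exp(s)))
    if family.family == "lognormal":
        return norm.logcdf(s)
    return s - np.logaddexp(0.0, s)


# ---------------------------------------------------------------------------
# linear predictors and probabilities
# ---------------------------------------------------------------------------


def linear_predictor(x, beta, z=0.0, submodel: str = "linear predictor"):
    """eta = x . beta + z for one covariate row (intercept included in x/beta)."""
    x = np.asarray(x, dtype=float)
    beta = np.asarray(beta, dtype=float)
    if x.shape[-1] != beta.shape[-1]:
        raise ValueError(
            f"{submodel}: covariate row has length {x.shape[-1]} "
            f"but coefficient vector has length {beta.shape[-1]}"
        )
    return x @ beta + z


def severity_prob(x, beta_S, z_S=0.0):
    """P(severe | covariates, z_S) under the logistic severity submodel."""
    return special.expit(linear_predictor(x, beta_S, z_S, submodel="severity submodel"))


def nonsusceptible_prob(x0, beta_ZI):
    """pi_i — probability of belonging to the latent non-susceptible class.

    Depends on baseline covariates only; the zero-inflation component carries
    no random effect.
    """
    return special.expit(
        linear_predictor(x0, beta_ZI, 0.0, submodel="zero-inflation submodel")
    )


# ---------------------------------------------------------------------------
# random-effects covariance parametrization
# ---------------------------------------------------------------------------


def _corr_cholesky(y):
    """Lower-triangular Cholesky factor of a correlation matrix from
    unconstrained reals via canonical partial correlations c = tanh(y).

    `y` is ordered ((1,0), (2,0), (2,1)) for a 3x3 matrix; any length
    d(d-1)/2 is accepted.
    """
    y = np.asarray(y, dtype=float)
    m = y.shape[0]
    d = int(round((1 + np.sqrt(1 + 8 * m)) / 2))
    c = np.tanh(y)
    L = np.zeros((d, d))
    L[0, 0] = 1.0
    k = 0
    for i in range(1, d):
        rem = 1.0
        for j in range(i):
            L[i, j] = c[k] * np.sqrt(rem)
            rem -= L[i, j] ** 2
            k += 1
        L[i, i] = np.sqrt(max(rem, 0.0))
    return L


def _corr_cholesky_inverse(R):
    """Unconstrained reals reproducing the correlation matrix R (inverse of
    :func:`_corr_cholesky`)."""
    L = np.linalg.cholesky(R)
    d = R.shape[0]
    y = []
    for i in range(1, d):
        rem = 1.0
        for j in range(i):
            c = L[i, j] / np.sqrt(rem)
            y.append(np.arctanh(np.clip(c, -1 + 1e-15, 1 - 1e-15)))
            rem -= L[i, j] ** 2
    return np.asarray(y)


def build_re_covariance(re_log_sd, re_corr_chol):
    """Random-effects covariance Sigma_Z from its unconstrained parameters.

    Returns ``(Sigma, sds, corrs)`` where `corrs` is ordered (B,W), (B,S),
    (W,S) for the 3-dimensional case.  Sigma is symmetric positive definite for
    every real input.
    """
    sds = np.exp(np.asarray(re_log_sd, dtype=float))
    L = _corr_cholesky(np.asarray(re_corr_chol, dtype=float))
    R = L @ L.T
    Sigma = np.outer(sds, sds) * R
    corrs = np.asarray([R[i, j] for i, j in _pairs(len(sds))])
    return Sigma, sds, corrs


def _pairs(d):
    """Pair order matching the row-wise Cholesky walk: (0,1), (0,2), (1,2)."""
    return [(j, i) for i in range(1, d) for j in range(i)]


def re_covariance_to_unconstrained(sds, corrs):
    """Inverse transform: (SDs, correlations) -> (re_log_sd, re_corr_chol)."""
    sds = np.asarray(sds, dtype=float)
    d = len(sds)
    R = np.eye(d)
    for k, (i, j) in enumerate(_pairs(d)):
        R[i, j] = R[j, i] = corrs[k]
    return np.log(sds), _corr_cholesky_inverse(R)


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass
class ExacerbationEpisode:
    """One completed exacerbation: onset/termination times since randomization
    (days), its duration W, and the binary severity mark S."""

    onset_time: float
    termination_time: float
    severity: int
    within_censored: int = 0

    @property
    def duration(self) -> float:
        return self.termination_time - self.onset_time

    def validate(self, subject_id="?") -> None:
        if not self.termination_time > self.onset_time:
            raise ValueError(
                f"subject {subject_id}: episode termination {self.termination_time} "
                f"not after onset {self.onset_time}"
            )
        if self.severity not in (0, 1):
            raise ValueError(f"subject {subject_id}: severity must be 0/1")
        if self.within_censored not in (0, 1):
            raise ValueError(f"subject {subject_id}: within_censored must be 0/1")


MIN_GAP = 1e-8  # days; continuous gap laws admit no zero gaps or ties


@dataclass
class SubjectHistory:
    """One patient's observed history over follow-up.

    The first exacerbation-free period is measured from randomization (the
    previous termination time is set to 0 by convention).  `final_gap` is the
    time from the last termination (or 0 if no events) to the end of the
    observed between-exacerbation time; in the default convention it is always
    censored.  `covariates` holds the baseline covariate values by name; the
    episode-specific counts N (prior exacerbations) and N_S (prior severe ones)
    are derived, not stored.
    """

    subject_id: object
    follow_up: float
    episodes: list = field(default_factory=list)
    final_gap: float = 0.0
    final_gap_censored: int = 1
    covariates: dict = field(default_factory=dict)

    @property
    def n_episodes(self) -> int:
        return len(self.episodes)

    def between_gaps(self) -> np.ndarray:
        """Completed between-exacerbation gaps B_j = U_j - V_{j-1}, V_0 = 0."""
        prev = 0.0
        out = []
        for ep in self.episodes:
            out.append(ep.onset_time - prev)
            prev = ep.termination_time
        return np.asarray(out)

    def episode_counts(self, include_final: bool = True):
        """Rows of derived episode covariates (N, N_S): one per episode, plus
        one for the final censored between-gap when `include_final`."""
        n_prior, n_prior_severe, rows = 0, 0, []
        for ep in self.episodes:
            rows.append((n_prior, n_prior_severe))
            n_prior += 1
            n_prior_severe += int(ep.severity)
        if include_final:
            rows.append((n_prior, n_prior_severe))
        return np.asarray(rows, dtype=float).reshape(-1, 2)

    def validate(self) -> None:
        prev = 0.0
        for j, ep in enumerate(self.episodes, start=1):
            ep.validate(self.subject_id)
            gap = ep.onset_time - prev
            if gap < MIN_GAP:
                raise ValueError(
                    f"subject {self.subject_id}: between-gap {j} is {gap} <= 0"
                )
            if ep.duration < MIN_GAP:
                raise ValueError(
                    f"subject {self.subject_id}: within-gap {j} is {ep.duration} <= 0"
                )
            prev = ep.termination_time
        if self.final_gap < 0:
            raise ValueError(f"subject {self.subject_id}: negative final gap")
        if self.final_gap_censored != 1:
            # follow-up ending exactly at an onset is not representable: the
            # trailing exacerbation-free time is always a censored gap
            raise ValueError(
                f"subject {self.subject_id}: the final between-gap must be "
                "censored (final_gap_censored = 1)"
            )
        if self.follow_up <= 0:
            raise ValueError(f"subject {self.subject_id}: non-positive follow-up")


@dataclass
class RandomEffects:
    """The trivariate random-effect point (z_B, z_W, z_S)."""

    z_B: float = 0.0
    z_W: float = 0.0
    z_S: float = 0.0

    def as_array(self) -> np.ndarray:
        return np.asarray([self.z_B, self.z_W, self.z_S], dtype=float)


@dataclass
class ModelParameters:
    """All free parameters of the joint model.

    Coefficient vectors include a leading intercept, so the baseline shape is
    purely a scale parameter.  The random-effects covariance is carried in the
    unconstrained parametrization (log SDs + correlation-Cholesky reals)
    ordered (B, W, S) and pairs (B,W), (B,S), (W,S).
    """

    beta_B: np.ndarray
    beta_W: np.ndarray
    beta_S: np.ndarray
    beta_ZI: np.ndarray
    shape_B: float = 1.0
    shape_W: float = 1.0
    re_log_sd: np.ndarray = field(default_factory=lambda: np.zeros(3))
    re_corr_chol: np.ndarray = field(default_factory=lambda: np.zeros(3))

    def __post_init__(self):
        self.beta_B = np.atleast_1d(np.asarray(self.beta_B, dtype=float))
        self.beta_W = np.atleast_1d(np.asarray(self.beta_W, dtype=float))
        self.beta_S = np.atleast_1d(np.asarray(self.beta_S, dtype=float))
        self.beta_ZI = np.atleast_1d(np.asarray(self.beta_ZI, dtype=float))
        self.re_log_sd = np.asarray(self.re_log_sd, dtype=float)
        self.re_corr_chol = np.asarray(self.re_corr_chol, dtype=float)

    def re_covariance(self):
        return build_re_covariance(self.re_log_sd, self.re_corr_chol)

    @property
    def re_sds(self) -> np.ndarray:
        return np.exp(self.re_log_sd)

    def copy(self) -> "ModelParameters":
        return ModelParameters(
            beta_B=self.beta_B.copy(),
            beta_W=self.beta_W.copy(),
            beta_S=self.beta_S.copy(),
            beta_ZI=self.beta_ZI.copy(),
            shape_B=self.shape_B,
            shape_W=self.shape_W,
            re_log_sd=self.re_log_sd.copy(),
            re_corr_chol=self.re_corr_chol.copy(),
        )


def design_row(covariates: dict, names, subject_id="?") -> np.ndarray:
    """Covariate row [1, x_1, ..., x_p] for the named columns."""
    try:
        vals = [float(covariates[n]) for n in names]
    except KeyError as err:
        raise KeyError(f"subject {subject_id}: missing covariate {err.args[0]!r}")
    return np.asarray([1.0, *vals])
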