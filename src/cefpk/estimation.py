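"""SAEM estimation of the population PK model.

The hierarchical model: per subject i, log individual parameters
``psi_i ~ N(X_i beta, Omega)`` (log-normal parameters with power-law
covariate links), and observations
``y_ij = F(t_ij, psi_i) + (a + b F) eps_ij`` with standard-normal eps.

Estimation follows the stochastic-approximation EM scheme used by the main
pharmacometric engines: an E-step that runs a few Metropolis-within-Gibbs
transitions on each subject's psi_i, a stochastic-approximation update of
the complete-data sufficient statistics, and an exact M-step for the
linear-Gaussian latent layer (GLS for beta, structured covariance for
Omega) plus the residual-error parameters.  Two step-size phases are used:
gamma=1 during exploration (with a simulated-annealing floor keeping the
variances from collapsing early) and gamma = k^-alpha during smoothing.

The marginal likelihood is computed afterwards by importance sampling with
per-subject Laplace proposals centred at the empirical Bayes estimates, and
the BIC from it.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from scipy.special import logsumexp

from .core_model import (
    PARAM_NAMES,
    ConfigurationError,
    ErrorSpec,
    RandomEffectSpec,
)
from .covariates import CovariateLink, SelectionTrace
from .data import EventDataset, Packed

logger = logging.getLogger("cefpk")

_LOG2PI = float(np.log(2.0 * np.pi))


# ---------------------------------------------------------------------------
# model containers
# ---------------------------------------------------------------------------

@dataclass
class PopulationModel:
    """A fully specified population model: fixed effects, links, Omega, error."""

    n_compartments: int
    theta: dict                      # param name -> typical value
    links: tuple = ()                # CovariateLink with fitted coefficients
    omega: RandomEffectSpec = None   # log-scale SDs, canonical order
    error: ErrorSpec = None
    error_model: str = "proportional"

    def __post_init__(self):
        if self.n_compartments not in PARAM_NAMES:
            raise ConfigurationError(f"unsupported compartment count {self.n_compartments}")
        self.links = tuple(self.links)
        if self.omega is None:
            self.omega = RandomEffectSpec(omega=(0.0,) * len(self.param_names))
        if self.error is None:
            self.error = ErrorSpec(a=0.0, b=0.12)

    @property
    def param_names(self) -> tuple:
        return PARAM_NAMES[self.n_compartments]

    def theta_vector(self) -> np.ndarray:
        return np.array([self.theta[p] for p in self.param_names])

    def design(self, covariate_sets) -> np.ndarray:
        """Per-subject design matrices X_i mapping beta to mean log parameters."""
        P = len(self.param_names)
        nb = P + len(self.links)
        X = np.zeros((len(covariate_sets), P, nb))
        X[:, np.arange(P), np.arange(P)] = 1.0
        for l, link in enumerate(self.links):
            p = self.param_names.index(link.parameter)
            for i, cov in enumerate(covariate_sets):
                X[i, p, P + l] = link.regressor(cov)
        return X

    def beta_vector(self) -> np.ndarray:
        return np.concatenate([
            np.log(self.theta_vector()),
            [link.coefficient for link in self.links],
        ])

    @classmethod
    def from_beta(cls, n_compartments, beta, links, omega, error, error_model):
        names = PARAM_NAMES[n_compartments]
        P = len(names)
        theta = {p: float(np.exp(beta[i])) for i, p in enumerate(names)}
        fitted_links = tuple(
            link.with_coefficient(beta[P + l]) for l, link in enumerate(links)
        )
        return cls(n_compartments, theta, fitted_links, omega, error, error_model)

    def mean_log_params(self, covariate_sets) -> np.ndarray:
        return self.design(covariate_sets) @ self.beta_vector()


@dataclass(frozen=True)
class ModelSpec:
    """What to estimate: structure, covariate links, error model, correlation."""

    n_compartments: int = 2
    links: tuple = ()
    error_model: str = "proportional"   # 'proportional' | 'additive' | 'combined'
    correlate_cl_vc: bool = True
    init: PopulationModel | None = None

    def __post_init__(self):
        if self.error_model not in ("proportional", "additive", "combined"):
            raise ConfigurationError(f"unknown error model {self.error_model!r}")
        object.__setattr__(self, "links", tuple(self.links))

    @property
    def n_estimated(self) -> int:
        P = len(PARAM_NAMES[self.n_compartments])
        n_err = 2 if self.error_model == "combined" else 1
        return P + len(self.links) + P + int(self.correlate_cl_vc) + n_err


@dataclass(frozen=True)
class SAEMSettings:
    """Tuning knobs of the SAEM run; defaults follow common engine practice."""

    n_exploration: int = 300
    n_smoothing: int = 200
    n_kernel: int = 5                 # MCMC transitions per subject per iteration
    step_exponent: float = 0.7        # gamma_k = (k - K1)^-alpha in phase 2
    anneal_tau: float = 0.95          # variance floor decay during exploration
    seed: int | None = None
    ll_samples: int = 2000            # importance samples for the final logL
    bic_n: str = "subjects"           # BIC sample-size convention
    compute_rse: bool = False

    def __post_init__(self):
        if self.n_exploration <= 0 or self.n_smoothing <= 0 or self.n_kernel <= 0:
            raise ConfigurationError("iteration counts must be positive")
        if not 0 < self.step_exponent <= 1:
            raise ConfigurationError("step-size exponent must lie in (0, 1]")
        if self.bic_n not in ("subjects", "observations"):
            raise ConfigurationError("bic_n must be 'subjects' or 'observations'")


@dataclass
class FitResult:
    """Everything the downstream stages need from one estimation run."""

    model: PopulationModel
    spec: ModelSpec
    settings: SAEMSettings
    loglik: float
    loglik_se: float
    bic: float
    n_params: int
    n_subjects: int
    n_obs: int
    n_blq_excluded: int
    ebes: pd.DataFrame
    shrinkage: dict
    rse: dict
    trace: pd.DataFrame
    converged: bool
    ebe_failures: list = field(default_factory=list)

    def omega_dict(self) -> dict:
        return dict(zip(self.model.param_names, self.model.omega.omega))

    def theta_dict(self) -> dict:
        out = dict(self.model.theta)
        for link in self.model.links:
            out[f"beta_{link.describe()}"] = link.coefficient
        return out

    def summary(self) -> pd.DataFrame:
        """Tabular parameter summary mirroring the usual popPK report layout."""
        rows = []
        for p in self.model.param_names:
            rows.append({"parameter": p, "estimate": self.model.theta[p],
                         "rse_pct": self.rse.get(p, np.nan)})
        for link in self.model.links:
            name = f"beta_{link.describe()}"
            rows.append({"parameter": name, "estimate": link.coefficient,
                         "rse_pct": self.rse.get(name, np.nan)})
        for p, w in self.omega_dict().items():
            rows.append({"parameter": f"omega_{p}", "estimate": w,
                         "rse_pct": self.rse.get(f"omega_{p}", np.nan),
                         "shrinkage_pct": self.shrinkage.get(p, np.nan)})
        rows.append({"parameter": "corr_cl_vc", "estimate": self.model.omega.corr_cl_vc,
                     "rse_pct": self.rse.get("corr_cl_vc", np.nan)})
        rows.append({"parameter": "error_a", "estimate": self.model.error.a,
                     "rse_pct": self.rse.get("error_a", np.nan)})
        rows.append({"parameter": "error_b", "estimate": self.model.error.b,
                     "rse_pct": self.rse.get("error_b", np.nan)})
        rows.append({"parameter": "loglik", "estimate": self.loglik})
        rows.append({"parameter": "BIC", "estimate": self.bic})
        return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# vectorized likelihood engine
# ---------------------------------------------------------------------------

def _exp_terms_psi(psi: np.ndarray, K: int):
    """lam, w of the unit-bolus solution for log-parameter array psi (..., P)."""
    from .core_model import exp_terms

    p = np.exp(psi)
    if K == 1:
        return exp_terms(p[..., 0], p[..., 1])
    return exp_terms(p[..., 0], p[..., 1], p[..., 2::2], p[..., 3::2])


def predict_conc(psi: np.ndarray, packed: Packed, K: int) -> np.ndarray:
    """Model-predicted concentration at every observation time.

    ``psi`` has shape (N, P) or (N, M, P); the result has shape (N, J) or
    (N, M, J) matching ``packed.t_obs``.
    """
    squeeze = psi.ndim == 2
    if squeeze:
        psi = psi[:, None, :]
    lam, w = _exp_terms_psi(psi, K)                      # (N, M, K)
    dt = packed.t_obs[:, None, :] - packed.dose_t[:, :, None]   # (N, D, J)
    active = (dt >= 0) & (packed.dose_amt[:, :, None] > 0)
    dt = np.where(active, dt, 0.0)
    # (N, M, D, J, K)
    E = np.exp(lam[:, :, None, None, :] * dt[:, None, :, :, None])
    conc = np.einsum("nmdjk,nmk,ndj,nd->nmj", E, w, active.astype(float), packed.dose_amt)
    return conc[:, 0, :] if squeeze else conc


def _obs_loglik(psi, packed: Packed, error: ErrorSpec, K: int) -> np.ndarray:
    """Per-subject observation log-likelihood, BLQ records excluded.

    Shapes as in :func:`predict_conc`; returns (N,) or (N, M).
    """
    squeeze = psi.ndim == 2
    conc = predict_conc(psi if not squeeze else psi[:, None, :], packed, K)
    sd = np.maximum(error.a + error.b * conc, 1e-12)
    mask = packed.obs_mask[:, None, :]
    y = np.where(packed.obs_mask, packed.y, 0.0)[:, None, :]
    with np.errstate(divide="ignore", invalid="ignore", over="ignore"):
        ll = -0.5 * _LOG2PI - np.log(sd) - 0.5 * ((y - conc) / sd) ** 2
    out = np.where(mask, ll, 0.0).sum(axis=-1)
    return out[:, 0] if squeeze else out


def _prior_loglik(psi, mu, omega_inv, omega_logdet) -> np.ndarray:
    """log N(psi; mu, Omega) per subject; psi (N,P) or (N,M,P), mu (N,P)."""
    if psi.ndim == 3:
        r = psi - mu[:, None, :]
    else:
        r = psi - mu
    quad = np.einsum("...p,pq,...q->...", r, omega_inv, r)
    P = mu.shape[-1]
    return -0.5 * (P * _LOG2PI + omega_logdet + quad)


# ---------------------------------------------------------------------------
# initial values (NCA-style heuristics)
# ---------------------------------------------------------------------------

def initial_estimates(data: EventDataset, n_compartments: int) -> dict:
    """Rough typical values from non-compartmental heuristics.

    Central volume from dose over Cmax; elimination from the terminal
    log-linear slope.  These only need to be in the right ballpark — SAEM
    with annealing is robust to a factor of a few.
    """
    packed = data.pack()
    y = np.where(packed.obs_mask, packed.y, np.nan)
    first_dose = packed.dose_amt[:, 0]
    with np.errstate(invalid="ignore"):
        cmax = np.nanmax(y, axis=1)
    ok = np.isfinite(cmax) & (cmax > 0)
    vc0 = float(np.median(first_dose[ok] / cmax[ok])) if ok.any() else 10.0
    slopes = []
    for i in range(packed.n_subjects):
        yy, tt = y[i], packed.t_obs[i]
        good = np.isfinite(yy) & (yy > 0)
        if good.sum() >= 2:
            y2, t2 = yy[good][-2:], tt[good][-2:]
            if t2[1] > t2[0] and y2[0] > y2[1]:
                slopes.append((np.log(y2[0]) - np.log(y2[1])) / (t2[1] - t2[0]))
    kel = float(np.median(slopes)) if slopes else 0.3
    kel = max(kel, 0.02)
    cl0 = kel * vc0 * (2.0 if n_compartments > 1 else 1.0)
    theta = {"cl": cl0, "vc": vc0}
    if n_compartments == 2:
        theta.update({"q": cl0, "vp": vc0})
    elif n_compartments == 3:
        theta.update({"q1": cl0, "vp1": vc0, "q2": 0.5 * cl0, "vp2": 0.5 * vc0})
    return theta


# ---------------------------------------------------------------------------
# SAEM
# ---------------------------------------------------------------------------

def _structure_omega(cov_full: np.ndarray, correlate: bool) -> np.ndarray:
    """Project the full sample covariance onto the model's block structure."""
    out = np.diag(np.diag(cov_full).copy())
    if correlate and cov_full.shape[0] >= 2:
        out[0, 1] = out[1, 0] = cov_full[0, 1]
    return out


def _clip_corr(om: np.ndarray, max_corr=0.98) -> np.ndarray:
    if om.shape[0] >= 2 and om[0, 1] != 0:
        bound = max_corr * np.sqrt(om[0, 0] * om[1, 1])
        om[0, 1] = om[1, 0] = np.clip(om[0, 1], -bound, bound)
    return om


def saem_fit(data: EventDataset, spec: ModelSpec = ModelSpec(),
             settings: SAEMSettings = SAEMSettings()) -> FitResult:
    """Maximum-likelihood estimation of the population model by SAEM.

    Reproducible bit-for-bit given ``settings.seed``.  Returns a
    :class:`FitResult` including EBEs, shrinkage, the importance-sampled
    log-likelihood and the BIC.
    """
    rng = np.random.default_rng(settings.seed)
    packed = data.pack()
    if packed.blq_mask.any():
        logger.warning("BLQ_EXCLUDED n=%d", int(packed.blq_mask.sum()))
    N = packed.n_subjects
    K = spec.n_compartments
    names = PARAM_NAMES[K]
    P = len(names)
    covs = [data.covariates[sid] for sid in packed.ids]

    # initial population values
    if spec.init is not None:
        init_model = spec.init
    else:
        init_model = PopulationModel(
            K, initial_estimates(data, K), links=spec.links,
            omega=RandomEffectSpec(omega=(0.3,) * P),
            error=ErrorSpec(a=1.0 if spec.error_model != "proportional" else 0.0,
                            b=0.2 if spec.error_model != "additive" else 0.0),
            error_model=spec.error_model,
        )
    work = PopulationModel(K, dict(init_model.theta), links=spec.links,
                           omega=init_model.omega, error=init_model.error,
                           error_model=spec.error_model)
    X = work.design(covs)                     # (N, P, nb)
    beta = work.beta_vector().copy()
    omega = work.omega.covariance().copy()
    np.fill_diagonal(omega, np.maximum(np.diag(omega), 1e-4))
    err_a, err_b = work.error.a, work.error.b

    mu = X @ beta
    psi = mu + 0.1 * rng.standard_normal((N, P))
    step_scale = np.full(N, 0.4)

    # SA sufficient statistics
    psi_bar = psi.copy()
    S2 = psi[:, :, None] * psi[:, None, :]
    S2 = S2.sum(axis=0)
    n_obs = packed.n_obs
    s_prop = 0.0
    s_add = 0.0
    f_bar = np.zeros_like(packed.y)
    r2_bar = np.zeros_like(packed.y)

    K1 = settings.n_exploration
    n_iter = K1 + settings.n_smoothing
    trace = np.zeros((n_iter, len(beta) + P + 3))
    error_spec = ErrorSpec(err_a, err_b)

    omega_inv = np.linalg.inv(omega)
    omega_logdet = float(np.linalg.slogdet(omega)[1])
    L_om = np.linalg.cholesky(omega)
    ll_obs_cur = _obs_loglik(psi, packed, error_spec, K)

    for k in range(1, n_iter + 1):
        ll_pri_cur = _prior_loglik(psi, mu, omega_inv, omega_logdet)

        # ---- E-step: Metropolis-within-Gibbs transitions per subject
        for m in range(settings.n_kernel):
            if m == 0:
                # independence kernel: propose from the prior
                prop = mu + rng.standard_normal((N, P)) @ L_om.T
                ll_obs_prop = _obs_loglik(prop, packed, error_spec, K)
                log_alpha = ll_obs_prop - ll_obs_cur
                accept = np.log(rng.random(N)) < log_alpha
                psi = np.where(accept[:, None], prop, psi)
                ll_obs_cur = np.where(accept, ll_obs_prop, ll_obs_cur)
                ll_pri_cur = _prior_loglik(psi, mu, omega_inv, omega_logdet)
            else:
                # random-walk kernel shaped by the current Omega
                prop = psi + step_scale[:, None] * (rng.standard_normal((N, P)) @ L_om.T)
                ll_obs_prop = _obs_loglik(prop, packed, error_spec, K)
                ll_pri_prop = _prior_loglik(prop, mu, omega_inv, omega_logdet)
                log_alpha = ll_obs_prop + ll_pri_prop - ll_obs_cur - ll_pri_cur
                accept = np.log(rng.random(N)) < log_alpha
                psi = np.where(accept[:, None], prop, psi)
                ll_obs_cur = np.where(accept, ll_obs_prop, ll_obs_cur)
                ll_pri_cur = np.where(accept, ll_pri_prop, ll_pri_cur)
                step_scale *= np.exp(0.08 * (accept.astype(float) - 0.3))
        step_scale = np.clip(step_scale, 0.02, 5.0)

        # ---- stochastic approximation of sufficient statistics
        gamma = 1.0 if k <= K1 else (k - K1) ** (-settings.step_exponent)
        psi_bar += gamma * (psi - psi_bar)
        S2 += gamma * ((psi[:, :, None] * psi[:, None, :]).sum(axis=0) - S2)
        conc = predict_conc(psi, packed, K)
        f = np.where(packed.obs_mask, np.maximum(conc, 1e-8), 1.0)
        resid = np.where(packed.obs_mask, packed.y - conc, 0.0)
        if spec.error_model == "proportional":
            s_prop += gamma * (float(((resid / f) ** 2).sum()) - s_prop)
        elif spec.error_model == "additive":
            s_add += gamma * (float((resid**2).sum()) - s_add)
        else:
            f_bar += gamma * (np.where(packed.obs_mask, f, 0.0) - f_bar)
            r2_bar += gamma * (resid**2 - r2_bar)

        # ---- M-step: GLS for beta, structured covariance for Omega
        A = np.einsum("npb,pq,nqc->bc", X, omega_inv, X)
        rhs = np.einsum("npb,pq,nq->b", X, omega_inv, psi_bar)
        beta = np.linalg.solve(A, rhs)
        mu = X @ beta
        M1 = mu.T @ psi_bar
        omega_full = (S2 - M1 - M1.T + mu.T @ mu) / N
        omega_new = _structure_omega(omega_full, spec.correlate_cl_vc)
        if k <= K1:  # simulated-annealing floor: variances shrink slowly
            floor = settings.anneal_tau * np.diag(omega)
            d = np.maximum(np.diag(omega_new), floor)
            if spec.correlate_cl_vc and P >= 2 and omega_new[0, 0] > 0 and omega_new[1, 1] > 0:
                corr = omega_new[0, 1] / np.sqrt(omega_new[0, 0] * omega_new[1, 1])
                omega_new[0, 1] = omega_new[1, 0] = corr * np.sqrt(d[0] * d[1])
            np.fill_diagonal(omega_new, d)
        np.fill_diagonal(omega_new, np.maximum(np.diag(omega_new), 1e-8))
        omega = _clip_corr(omega_new)
        omega_inv = np.linalg.inv(omega)
        omega_logdet = float(np.linalg.slogdet(omega)[1])
        L_om = np.linalg.cholesky(omega)

        # ---- residual-error update
        if spec.error_model == "proportional":
            b_new = np.sqrt(s_prop / n_obs)
            if k <= K1:
                b_new = max(b_new, np.sqrt(settings.anneal_tau) * err_b)
            err_b = max(b_new, 1e-6)
        elif spec.error_model == "additive":
            a_new = np.sqrt(s_add / n_obs)
            if k <= K1:
                a_new = max(a_new, np.sqrt(settings.anneal_tau) * err_a)
            err_a = max(a_new, 1e-6)
        else:
            err_a, err_b = _fit_combined_error(f_bar, r2_bar, packed.obs_mask, err_a, err_b)
            if k <= K1:
                err_a = max(err_a, np.sqrt(settings.anneal_tau) * error_spec.a)
                err_b = max(err_b, np.sqrt(settings.anneal_tau) * error_spec.b)
        error_spec = ErrorSpec(err_a, err_b)

        trace[k - 1] = np.concatenate([
            beta, np.sqrt(np.diag(omega)),
            [omega[0, 1] / np.sqrt(omega[0, 0] * omega[1, 1]) if P >= 2 else 0.0,
             err_a, err_b],
        ])

    # ---- assemble the fitted model
    om_sd = np.sqrt(np.diag(omega))
    corr = float(omega[0, 1] / (om_sd[0] * om_sd[1])) if (P >= 2 and spec.correlate_cl_vc) else 0.0
    re_spec = RandomEffectSpec(omega=tuple(om_sd), corr_cl_vc=corr)
    model = PopulationModel.from_beta(K, beta, spec.links, re_spec,
                                      ErrorSpec(err_a, err_b), spec.error_model)

    trace_cols = ([f"log_theta_{p}" for p in names]
                  + [f"beta_{l.describe()}" for l in spec.links]
                  + [f"omega_{p}" for p in names]
                  + ["corr_cl_vc", "error_a", "error_b"])
    trace_df = pd.DataFrame(trace, columns=trace_cols)
    trace_df.insert(0, "iteration", np.arange(1, n_iter + 1))

    # convergence heuristic: relative drift of theta over the last smoothing half
    tail = trace[-max(settings.n_smoothing // 2, 10):, : len(beta)]
    drift = np.abs(tail[-1] - tail[0]) / np.maximum(np.abs(tail[-1]), 1e-6)
    converged = bool(np.all(drift < 0.10))
    if not converged:
        logger.warning("SAEM_DRIFT max_rel_change=%.3f", float(drift.max()))

    ebes, failures = empirical_bayes(data, model, packed=packed)
    shrink = shrinkage(ebes, dict(zip(names, om_sd)))
    ll, ll_se = log_likelihood(data, model, n_samples=settings.ll_samples,
                               seed=rng.integers(2**31), ebes=ebes, packed=packed)
    n_for_bic = N if settings.bic_n == "subjects" else packed.n_obs
    k_params = spec.n_estimated
    bic_value = bic(ll, k_params, n_for_bic)

    fit = FitResult(
        model=model, spec=spec, settings=settings,
        loglik=ll, loglik_se=ll_se, bic=bic_value, n_params=k_params,
        n_subjects=N, n_obs=packed.n_obs, n_blq_excluded=int(packed.blq_mask.sum()),
        ebes=ebes, shrinkage=shrink, rse={}, trace=trace_df,
        converged=converged, ebe_failures=failures,
    )
    if settings.compute_rse:
        fit.rse = standard_errors(data, fit, seed=int(rng.integers(2**31)))
    return fit


def _fit_combined_error(f_bar, r2_bar, mask, a0, b0):
    """M-step for the combined error model on SA-averaged per-record moments."""
    f = f_bar[mask]
    r2 = r2_bar[mask]

    def nll(x):
        a, b = np.exp(x)
        sd = a + b * f
        return float(np.sum(np.log(sd) + 0.5 * r2 / sd**2))

    res = minimize(nll, np.log([max(a0, 1e-3), max(b0, 1e-3)]), method="Nelder-Mead",
                   options={"xatol": 1e-4, "fatol": 1e-6, "maxiter": 200})
    a, b = np.exp(res.x)
    return float(a), float(b)


# ---------------------------------------------------------------------------
# empirical Bayes estimates and shrinkage
# ---------------------------------------------------------------------------

def empirical_bayes(data: EventDataset, model: PopulationModel, packed: Packed = None):
    """Per-subject posterior modes of eta (psi = mu_i + eta).

    Gradient-based maximization of the joint density starting from eta=0;
    a failed optimization returns eta=0 for that subject and flags it.
    Subjects with no usable observations sit at the prior mode eta=0.
    """
    packed = packed or data.pack()
    covs = [data.covariates[sid] for sid in packed.ids]
    mu = model.mean_log_params(covs)
    K = model.n_compartments
    P = len(model.param_names)
    omega = model.omega.covariance()
    np.fill_diagonal(omega, np.maximum(np.diag(omega), 1e-10))
    om_inv = np.linalg.inv(omega)
    etas = np.zeros((packed.n_subjects, P))
    failures = []
    one = Packed(packed.ids[:1], packed.y[:1], packed.t_obs[:1], packed.obs_mask[:1],
                 packed.blq_mask[:1], packed.dose_amt[:1], packed.dose_t[:1])
    for i in range(packed.n_subjects):
        if not packed.obs_mask[i].any():
            continue
        one = Packed(packed.ids[i:i + 1], packed.y[i:i + 1], packed.t_obs[i:i + 1],
                     packed.obs_mask[i:i + 1], packed.blq_mask[i:i + 1],
                     packed.dose_amt[i:i + 1], packed.dose_t[i:i + 1])
        mu_i = mu[i]

        def nll(eta):
            psi = (mu_i + eta)[None, :]
            return float(-_obs_loglik(psi, one, model.error, K)[0]
                         + 0.5 * eta @ om_inv @ eta)

        res = minimize(nll, np.zeros(P), method="BFGS",
                       options={"gtol": 1e-6, "maxiter": 200})
        if np.all(np.isfinite(res.x)) and res.fun <= nll(np.zeros(P)) + 1e-9:
            etas[i] = res.x
        else:
            failures.append(packed.ids[i])
            logger.warning("EBE_FALLBACK subject=%s", packed.ids[i])
    return (pd.DataFrame(etas, index=pd.Index(packed.ids, name="ID"),
                         columns=[f"eta_{p}" for p in model.param_names]),
            failures)


def shrinkage(ebes: pd.DataFrame, omega: dict) -> dict:
    """Eta-shrinkage per parameter: 100 * (1 - SD(EBE)/omega); NaN where omega=0."""
    out = {}
    for p, w in omega.items():
        col = f"eta_{p}"
        if w <= 0 or col not in ebes.columns or len(ebes) < 2:
            out[p] = np.nan
        else:
            out[p] = float(100.0 * (1.0 - ebes[col].std(ddof=1) / w))
    return out


# ---------------------------------------------------------------------------
# marginal likelihood, BIC
# ---------------------------------------------------------------------------

def bic(loglik: float, n_params: int, n: int) -> float:
    """Bayesian information criterion: -2 logL + k ln(n). Lower is better."""
    if n_params < 0:
        raise ConfigurationError("parameter count must be non-negative")
    return float(-2.0 * loglik + n_params * np.log(n)) if n_params else float(-2.0 * loglik)


def _laplace_proposals(packed, mu, model, ebes_arr, h=1e-3):
    """Per-subject proposal covariances from a numeric Hessian at the EBE mode."""
    K = model.n_compartments
    P = mu.shape[1]
    omega = model.omega.covariance()
    np.fill_diagonal(omega, np.maximum(np.diag(omega), 1e-10))
    om_inv = np.linalg.inv(omega)
    logdet = float(np.linalg.slogdet(omega)[1])
    psi_hat = mu + ebes_arr

    def f(psi):
        return -(_obs_loglik(psi, packed, model.error, K)
                 + _prior_loglik(psi, mu, om_inv, logdet))

    H = np.zeros((packed.n_subjects, P, P))
    eye = np.eye(P)
    f0 = f(psi_hat)
    for a in range(P):
        fp = f(psi_hat + h * eye[a])
        fm = f(psi_hat - h * eye[a])
        H[:, a, a] = (fp - 2 * f0 + fm) / h**2
        for b in range(a + 1, P):
            fpp = f(psi_hat + h * eye[a] + h * eye[b])
            fpm = f(psi_hat + h * eye[a] - h * eye[b])
            fmp = f(psi_hat - h * eye[a] + h * eye[b])
            fmm = f(psi_hat - h * eye[a] - h * eye[b])
            H[:, a, b] = H[:, b, a] = (fpp - fpm - fmp + fmm) / (4 * h**2)
    # make each Hessian safely positive definite, then invert
    vals, vecs = np.linalg.eigh(H)
    vals = np.maximum(vals, 1e-4)
    cov = np.einsum("nab,nb,ncb->nac", vecs, 1.0 / vals, vecs)
    return psi_hat, cov


def log_likelihood(data: EventDataset, model: PopulationModel, n_samples: int = 2000,
                   seed=None, ebes: pd.DataFrame = None, packed: Packed = None):
    """Importance-sampling estimate of the marginal log-likelihood.

    The proposal is a per-subject Gaussian centred at the EBE mode with the
    local Laplace covariance; a degenerate Hessian falls back to the prior
    covariance.  Returns ``(logL, Monte-Carlo SE)``.
    """
    rng = np.random.default_rng(seed)
    packed = packed or data.pack()
    covs = [data.covariates[sid] for sid in packed.ids]
    mu = model.mean_log_params(covs)
    P = mu.shape[1]
    if ebes is None:
        ebes, _ = empirical_bayes(data, model, packed=packed)
    ebes_arr = ebes.to_numpy()
    omega = model.omega.covariance()
    np.fill_diagonal(omega, np.maximum(np.diag(omega), 1e-10))
    om_inv = np.linalg.inv(omega)
    om_logdet = float(np.linalg.slogdet(omega)[1])
    try:
        centers, prop_cov = _laplace_proposals(packed, mu, model, ebes_arr)
    except np.linalg.LinAlgError:
        logger.warning("LAPLACE_PROPOSAL_FALLBACK using prior covariance")
        centers = mu + ebes_arr
        prop_cov = np.broadcast_to(omega, (packed.n_subjects, P, P)).copy()
    L = np.linalg.cholesky(prop_cov)
    prop_logdet = 2.0 * np.log(np.einsum("naa->na", L)).sum(axis=1)

    z = rng.standard_normal((packed.n_subjects, n_samples, P))
    psi = centers[:, None, :] + np.einsum("nab,nmb->nma", L, z)
    ll = (_obs_loglik(psi, packed, model.error, model.n_compartments)
          + _prior_loglik(psi, mu, om_inv, om_logdet))
    log_q = -0.5 * (P * _LOG2PI + prop_logdet[:, None] + (z**2).sum(axis=2))
    log_w = ll - log_q                                        # (N, M)
    log_li = logsumexp(log_w, axis=1) - np.log(n_samples)
    # delta-method MC standard error on the log scale
    wn = np.exp(log_w - log_li[:, None] - np.log(n_samples))  # normalized weights
    se_i = np.sqrt(np.maximum((wn**2).sum(axis=1) - 1.0 / n_samples, 0.0))
    return float(log_li.sum()), float(np.sqrt((se_i**2).sum()))


# ---------------------------------------------------------------------------
# standard errors (numerically differentiated IS likelihood)
# ---------------------------------------------------------------------------

def standard_errors(data: EventDataset, fit: FitResult, n_samples: int = 500,
                    seed=None, h: float = 0.01) -> dict:
    """Relative standard errors (%) of all estimated parameters.

    Observed information is obtained by finite-differencing the
    importance-sampled log-likelihood under common random numbers (fixed
    proposal and fixed standard-normal draws), which makes the mapping from
    parameters to the estimated logL smooth and differencable.
    """
    rng = np.random.default_rng(seed)
    model = fit.model
    spec = fit.spec
    packed = data.pack()
    covs = [data.covariates[sid] for sid in packed.ids]
    names = model.param_names
    P = len(names)

    mu = model.mean_log_params(covs)
    ebes_arr = fit.ebes.to_numpy()
    centers, prop_cov = _laplace_proposals(packed, mu, model, ebes_arr)
    L = np.linalg.cholesky(prop_cov)
    prop_logdet = 2.0 * np.log(np.einsum("naa->na", L)).sum(axis=1)
    z = rng.standard_normal((packed.n_subjects, n_samples, P))
    psi = centers[:, None, :] + np.einsum("nab,nmb->nma", L, z)
    log_q = -0.5 * (P * _LOG2PI + prop_logdet[:, None] + (z**2).sum(axis=2))

    # parameter vector on unconstrained scales
    labels = ([p for p in names] + [f"beta_{l.describe()}" for l in model.links]
              + [f"omega_{p}" for p in names])
    vec = list(np.log(model.theta_vector())) + [l.coefficient for l in model.links] \
        + list(np.log(np.maximum(model.omega.omega, 1e-8)))
    if spec.correlate_cl_vc:
        labels.append("corr_cl_vc")
        vec.append(np.arctanh(np.clip(model.omega.corr_cl_vc, -0.999, 0.999)))
    if spec.error_model in ("additive", "combined"):
        labels.append("error_a")
        vec.append(np.log(max(model.error.a, 1e-8)))
    if spec.error_model in ("proportional", "combined"):
        labels.append("error_b")
        vec.append(np.log(max(model.error.b, 1e-8)))
    vec = np.asarray(vec)
    n_par = len(vec)
    X = model.design(covs)

    def loglik_at(v):
        i = 0
        beta = np.concatenate([v[:P], v[P:P + len(model.links)]])
        i = P + len(model.links)
        om_sd = np.exp(v[i:i + P]); i += P
        corr = float(np.tanh(v[i])) if spec.correlate_cl_vc else 0.0
        i += int(spec.correlate_cl_vc)
        a = float(np.exp(v[i])) if spec.error_model in ("additive", "combined") else 0.0
        i += int(spec.error_model in ("additive", "combined"))
        b = float(np.exp(v[i])) if spec.error_model in ("proportional", "combined") else 0.0
        omega = np.diag(om_sd**2)
        if P >= 2:
            omega[0, 1] = omega[1, 0] = corr * om_sd[0] * om_sd[1]
        np.fill_diagonal(omega, np.maximum(np.diag(omega), 1e-12))
        om_inv = np.linalg.inv(omega)
        om_logdet = float(np.linalg.slogdet(omega)[1])
        mu_v = X @ beta
        err = ErrorSpec(a, b)
        ll = (_obs_loglik(psi, packed, err, model.n_compartments)
              + _prior_loglik(psi, mu_v, om_inv, om_logdet))
        log_w = ll - log_q
        return float((logsumexp(log_w, axis=1) - np.log(n_samples)).sum())

    # central-difference Hessian
    H = np.zeros((n_par, n_par))
    f0 = loglik_at(vec)
    eye = np.eye(n_par)
    for a_ in range(n_par):
        fp = loglik_at(vec + h * eye[a_])
        fm = loglik_at(vec - h * eye[a_])
        H[a_, a_] = (fp - 2 * f0 + fm) / h**2
        for b_ in range(a_ + 1, n_par):
            fpp = loglik_at(vec + h * (eye[a_] + eye[b_]))
            fpm = loglik_at(vec + h * (eye[a_] - eye[b_]))
            fmp = loglik_at(vec - h * (eye[a_] - eye[b_]))
            fmm = loglik_at(vec - h * (eye[a_] + eye[b_]))
            H[a_, b_] = H[b_, a_] = (fpp - fpm - fmp + fmm) / (4 * h**2)
    info = -H
    try:
        cov = np.linalg.inv(info)
    except np.linalg.LinAlgError:
        logger.warning("FISHER_SINGULAR ridge-regularizing")
        cov = np.linalg.inv(info + 1e-6 * np.eye(n_par))
    se = np.sqrt(np.maximum(np.diag(cov), 0.0))

    out = {}
    for lbl, v, s in zip(labels, vec, se):
        if lbl.startswith("beta_"):
            coef = v
            out[lbl] = float(100.0 * s / abs(coef)) if coef != 0 else np.nan
        elif lbl == "corr_cl_vc":
            rho = np.tanh(v)
            se_rho = s * (1 - rho**2)
            out[lbl] = float(100.0 * se_rho / abs(rho)) if rho != 0 else np.nan
        else:
            # log-scale parameter: SE of log x is already the relative SE
            out[lbl] = float(100.0 * s)
    return out


# ---------------------------------------------------------------------------
# structural model comparison
# ---------------------------------------------------------------------------

def compare_structural(data: EventDataset, settings: SAEMSettings = SAEMSettings(),
                       compartments=(1, 2, 3), error_model="proportional") -> SelectionTrace:
    """Fit 1-, 2- and 3-compartment covariate-free models and rank them by BIC."""
    trace = SelectionTrace()
    fits = {}
    for K in compartments:
        spec = ModelSpec(n_compartments=K, links=(), error_model=error_model,
                         correlate_cl_vc=True)
        try:
            fit = saem_fit(data, spec, settings)
        except Exception as exc:
            logger.warning("STRUCTURAL_FIT_FAILED compartments=%d reason=%s", K, exc)
            trace.add(f"{K}-compartment (failed)", np.inf, np.nan, {}, accepted=False)
            continue
        fits[K] = fit
        trace.add(f"{K}-compartment", fit.bic, np.nan, fit.omega_dict(), accepted=False)
    if fits:
        best = min(fits, key=lambda K: fits[K].bic)
        for s in trace.steps:
            s.accepted = s.description == f"{best}-compartment"
        trace.selected = fits[best]
    return trace
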