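"""Closed-form mammillary compartmental kinetics and the individual-parameter model.

This module is the mathematical heart of the package: analytic
sum-of-exponential solutions of the 1-, 2- and 3-compartment mammillary
model after intravenous bolus dosing, the log-normal covariate map that
turns population fixed effects plus subject-level random effects into
individual PK parameters, the combined (additive + proportional) residual
error model, and correlated random-effect sampling.

All kinetics are linear, so multiple doses superpose exactly.  Units are
fixed throughout the package: mg for amounts, L for volumes, h for time,
mg/L for concentrations.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

logger = logging.getLogger("cefpk")

#: canonical parameter names by compartment count
PARAM_NAMES = {
    1: ("cl", "vc"),
    2: ("cl", "vc", "q", "vp"),
    3: ("cl", "vc", "q1", "vp1", "q2", "vp2"),
}


class ConfigurationError(ValueError):
    """Raised for structurally invalid model configuration."""


class InputError(ValueError):
    """Raised for invalid numerical input (negative time, CrCL <= 0, ...)."""


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

def _as_tuple(x) -> tuple:
    if x is None:
        return ()
    return tuple(np.atleast_1d(np.asarray(x, dtype=float)).tolist())


@dataclass(frozen=True)
class PKParameters:
    """One subject's structural parameters of the mammillary bolus model.

    Parameters
    ----------
    cl : float
        Elimination clearance from the central compartment (L/h).
    vc : float
        Central volume of distribution (L).
    q : tuple of float
        Intercompartmental clearances, one per peripheral compartment (L/h).
    vp : tuple of float
        Peripheral volumes, one per peripheral compartment (L).
    """

    cl: float
    vc: float
    q: tuple = ()
    vp: tuple = ()

    def __post_init__(self):
        object.__setattr__(self, "q", _as_tuple(self.q))
        object.__setattr__(self, "vp", _as_tuple(self.vp))
        if len(self.q) != len(self.vp):
            raise ConfigurationError("q and vp must have one entry per peripheral compartment")
        if self.n_compartments not in (1, 2, 3):
            raise ConfigurationError(f"unsupported compartment count {self.n_compartments}")
        vals = (self.cl, self.vc) + self.q + self.vp
        if any(not np.isfinite(v) or v <= 0 for v in vals):
            raise InputError("all PK parameters must be positive and finite")

    @property
    def n_compartments(self) -> int:
        return 1 + len(self.q)

    def as_array(self) -> np.ndarray:
        out = [self.cl, self.vc]
        for qi, vi in zip(self.q, self.vp):
            out.extend([qi, vi])
        return np.asarray(out, dtype=float)

    @classmethod
    def from_array(cls, values: Sequence[float]) -> "PKParameters":
        values = np.asarray(values, dtype=float)
        if values.size not in (2, 4, 6):
            raise ConfigurationError("parameter vector must have length 2, 4 or 6")
        return cls(cl=values[0], vc=values[1], q=tuple(values[2::2]), vp=tuple(values[3::2]))


@dataclass(frozen=True)
class DoseEvent:
    """An instantaneous IV bolus: `amount` mg given at `time` h after the first dose."""

    time: float
    amount: float

    def __post_init__(self):
        if self.amount <= 0:
            raise InputError("dose amount must be positive")
        if self.time < 0:
            raise InputError("dose time must be non-negative")


@dataclass
class CovariateSet:
    """Per-subject covariates; derived quantities are filled by :mod:`cefpk.covariates`.

    ``scr`` is stored with an explicit unit (``umol/L`` or ``mg/dL``) because
    the two creatinine-clearance formulas conventionally use different units.
    """

    age: float | None = None
    sex: str | None = None          # "M" or "F"
    tbw: float | None = None        # total body weight, kg
    height: float | None = None     # m
    bmi: float | None = None        # kg/m^2
    scr: float | None = None        # serum creatinine
    scr_unit: str = "umol/L"
    crcl_cg: float | None = None    # Cockcroft-Gault, mL/min
    crcl_ckdepi: float | None = None  # CKD-EPI, mL/min/1.73 m^2
    lbw: float | None = None        # lean body weight, kg

    def __post_init__(self):
        if self.sex is not None and self.sex not in ("M", "F"):
            raise InputError(f"sex must be 'M' or 'F', got {self.sex!r}")
        if self.scr_unit not in ("umol/L", "mg/dL"):
            raise InputError(f"unknown creatinine unit {self.scr_unit!r}")
        if self.bmi is None and self.tbw is not None and self.height is not None:
            self.bmi = self.tbw / self.height**2
        if (
            self.bmi is not None
            and self.tbw is not None
            and self.height is not None
            and not np.isclose(self.bmi, self.tbw / self.height**2, rtol=0.02)
        ):
            raise InputError("bmi inconsistent with tbw/height^2")

    def scr_mg_dl(self) -> float:
        if self.scr is None:
            raise InputError("serum creatinine missing")
        return self.scr / 88.4 if self.scr_unit == "umol/L" else self.scr

    def scr_umol_l(self) -> float:
        if self.scr is None:
            raise InputError("serum creatinine missing")
        return self.scr if self.scr_unit == "umol/L" else self.scr * 88.4

    def get(self, name: str) -> float:
        """Numeric covariate lookup; sex is encoded as female=1, male=0."""
        if name == "sex":
            return float(self.sex == "F")
        value = getattr(self, name)
        if value is None:
            raise InputError(f"covariate {name!r} missing")
        return float(value)


@dataclass(frozen=True)
class FixedEffects:
    """Typical-value fixed effects of the final 2-compartment model.

    ``theta_crcl`` is the exponent of the power law linking creatinine
    clearance (centred on 80) to elimination clearance.
    """

    theta_cl: float
    theta_vc: float
    theta_q: float
    theta_vp: float
    theta_crcl: float = 0.0

    def __post_init__(self):
        if min(self.theta_cl, self.theta_vc, self.theta_q, self.theta_vp) <= 0:
            raise ConfigurationError("typical values must be positive")


@dataclass(frozen=True)
class RandomEffectSpec:
    """Log-scale between-subject variability.

    ``omega`` holds standard deviations of the log-normal random effects, in
    the canonical parameter order for the model's compartment count.  Only
    the CL-Vc pair may be correlated; all other off-diagonals are zero.
    """

    omega: tuple
    corr_cl_vc: float = 0.0

    def __post_init__(self):
        object.__setattr__(self, "omega", tuple(float(w) for w in np.atleast_1d(self.omega)))
        if any(w < 0 for w in self.omega):
            raise ConfigurationError("omegas must be non-negative")
        if not -1.0 <= self.corr_cl_vc <= 1.0:
            raise ConfigurationError("correlation must lie in [-1, 1]")

    @property
    def n_params(self) -> int:
        return len(self.omega)

    def covariance(self) -> np.ndarray:
        om = np.asarray(self.omega)
        cov = np.diag(om**2)
        if len(om) >= 2:
            cov[0, 1] = cov[1, 0] = self.corr_cl_vc * om[0] * om[1]
        # PSD is guaranteed by |corr| <= 1 and the block-diagonal structure,
        # up to round-off at |corr| == 1.
        return cov


@dataclass(frozen=True)
class ErrorSpec:
    """Residual error model: sd(obs | pred=f) = a + b*f.

    ``a`` is the additive component (mg/L), ``b`` the proportional component
    (dimensionless fraction).  The final cefazolin model is purely
    proportional (a = 0, b = 0.12).
    """

    a: float = 0.0
    b: float = 0.0

    def __post_init__(self):
        if self.a < 0 or self.b < 0:
            raise ConfigurationError("error components must be non-negative")
        if self.a == 0 and self.b == 0:
            raise ConfigurationError("error model cannot be identically zero")

    def sd(self, f):
        return self.a + self.b * np.asarray(f, dtype=float)


# ---------------------------------------------------------------------------
# exponential machinery
# ---------------------------------------------------------------------------

def exp_terms(cl, vc, q=None, vp=None):
    """Exponents and weights of the unit-bolus central concentration.

    For a unit (1 mg) bolus into the central compartment at t=0 the central
    concentration is ``c(t) = sum_k w_k * exp(lam_k * t)``.  Accepts scalars
    or broadcastable arrays for ``cl``/``vc`` and, for multi-compartment
    models, arrays whose last axis enumerates peripheral compartments.

    Returns
    -------
    lam, w : ndarray
        Shape ``(..., K)`` where K is the compartment count; ``lam`` are the
        (negative) exponents in 1/h and ``w`` the weights in 1/L.
    """
    cl = np.asarray(cl, dtype=float)
    vc = np.asarray(vc, dtype=float)
    if q is None or np.size(q) == 0:
        lam = (-cl / vc)[..., None]
        w = (1.0 / vc)[..., None]
        return lam, w
    q = np.atleast_1d(np.asarray(q, dtype=float))
    vp = np.atleast_1d(np.asarray(vp, dtype=float))
    n_per = q.shape[-1]
    if n_per == 1:
        # classic biexponential closed form
        q0 = q[..., 0]
        vp0 = vp[..., 0]
        k10 = cl / vc
        k12 = q0 / vc
        k21 = q0 / vp0
        s = k10 + k12 + k21
        p = k10 * k21
        disc = np.sqrt(np.maximum(s * s - 4.0 * p, 0.0))
        alpha = 0.5 * (s + disc)
        beta = 0.5 * (s - disc)
        denom = np.where(disc > 0, alpha - beta, 1.0)
        ca = (alpha - k21) / denom
        cb = (k21 - beta) / denom
        lam = np.stack([-alpha, -beta], axis=-1)
        w = np.stack([ca, cb], axis=-1) / vc[..., None]
        return lam, w
    if n_per == 2:
        return _exp_terms_eig(cl, vc, q, vp)
    raise ConfigurationError("at most two peripheral compartments are supported")


def _rate_matrix(cl, vc, q, vp):
    """Mammillary first-order rate matrix acting on compartment amounts."""
    cl = np.asarray(cl, dtype=float)
    vc = np.asarray(vc, dtype=float)
    n_per = q.shape[-1]
    K = n_per + 1
    shape = np.broadcast_shapes(cl.shape, vc.shape, q.shape[:-1])
    A = np.zeros(shape + (K, K))
    k10 = np.broadcast_to(cl / vc, shape)
    A[..., 0, 0] = -k10
    for m in range(n_per):
        k1m = q[..., m] / vc
        km1 = q[..., m] / vp[..., m]
        A[..., 0, 0] -= k1m
        A[..., 0, m + 1] = km1
        A[..., m + 1, 0] = k1m
        A[..., m + 1, m + 1] = -km1
    return A


def _exp_terms_eig(cl, vc, q, vp):
    A = _rate_matrix(cl, vc, q, vp)
    lam, V = np.linalg.eig(A)
    # mammillary matrices are similar to symmetric ones: spectrum is real
    lam = lam.real
    V = V.real
    c0 = np.linalg.solve(V, np.broadcast_to(np.eye(A.shape[-1])[:, 0], lam.shape)[..., None])[..., 0]
    w = V[..., 0, :] * c0 / np.asarray(vc, dtype=float)[..., None]
    return lam, w


def concentration(params: PKParameters, doses: Sequence[DoseEvent], t):
    """Central-compartment concentration at time(s) ``t`` after bolus dosing.

    Linear superposition over every dose administered at or before ``t``;
    an empty dose list yields 0 everywhere.
    """
    t_arr = np.asarray(t, dtype=float)
    if np.any(t_arr < 0):
        raise InputError("time must be non-negative")
    lam, w = exp_terms(params.cl, params.vc, params.q, params.vp)
    out = np.zeros(t_arr.shape)
    for d in doses:
        dt = t_arr - d.time
        active = dt >= 0
        if np.any(active):
            terms = w * np.exp(lam * np.where(active, dt, 0.0)[..., None])
            out += np.where(active, d.amount * terms.sum(axis=-1), 0.0)
    return out if np.ndim(t) else float(out)


def compartment_amounts(params: PKParameters, doses: Sequence[DoseEvent], t: float) -> np.ndarray:
    """Drug amount (mg) in each compartment at time ``t`` (central first).

    Used mainly for mass-balance checks: amounts plus the eliminated mass
    ``CL * integral of C`` must equal the total administered dose.
    """
    if t < 0:
        raise InputError("time must be non-negative")
    K = params.n_compartments
    A = _rate_matrix(
        np.asarray(params.cl), np.asarray(params.vc),
        np.asarray(params.q).reshape(-1) if params.q else np.zeros((0,)),
        np.asarray(params.vp).reshape(-1) if params.vp else np.zeros((0,)),
    )
    lam, V = np.linalg.eig(A)
    lam, V = lam.real, V.real
    amounts = np.zeros(K)
    e1 = np.eye(K)[:, 0]
    c0 = np.linalg.solve(V, e1)
    for d in doses:
        if d.time <= t:
            amounts += d.amount * (V * c0) @ np.exp(lam * (t - d.time))
    return amounts


# ---------------------------------------------------------------------------
# individual parameters, residual error, random effects
# ---------------------------------------------------------------------------

def individual_parameters(
    theta: FixedEffects,
    eta: Sequence[float],
    cov: CovariateSet,
    crcl_source: str = "crcl_ckdepi",
) -> PKParameters:
    """Map fixed effects + log-scale deviates + covariates to one subject's parameters.

    The final-model covariate structure: CL scales with creatinine clearance
    through a power law centred on 80, ``CL_i = theta_cl * (CrCL_i/80)**theta_crcl
    * exp(eta_cl)``; Vc, Q and Vp carry only their log-normal random effect.
    """
    eta = np.asarray(eta, dtype=float)
    if eta.size != 4:
        raise ConfigurationError("expected one eta per parameter (cl, vc, q, vp)")
    crcl = cov.get(crcl_source)
    if crcl <= 0:
        raise InputError("creatinine clearance must be positive")
    cl = theta.theta_cl * (crcl / 80.0) ** theta.theta_crcl * np.exp(eta[0])
    vc = theta.theta_vc * np.exp(eta[1])
    q = theta.theta_q * np.exp(eta[2])
    vp = theta.theta_vp * np.exp(eta[3])
    return PKParameters(cl=cl, vc=vc, q=(q,), vp=(vp,))


def observe(f, err: ErrorSpec, epsilon):
    """Apply the residual error model: ``obs = f + (a + b*f) * eps``."""
    f = np.asarray(f, dtype=float)
    if np.any(f < 0):
        raise InputError("predicted concentration must be non-negative")
    out = f + err.sd(f) * np.asarray(epsilon, dtype=float)
    return out if out.ndim else float(out)


def sample_etas(spec: RandomEffectSpec, n: int, seed=None) -> np.ndarray:
    """Draw ``n`` multivariate-normal eta vectors with the block covariance.

    Only the CL-Vc pair is correlated; the draw is reproducible given seed
    (an integer or a ``numpy.random.Generator``).
    """
    cov = spec.covariance()
    # guard against round-off at |corr| = 1
    eigmin = np.linalg.eigvalsh(cov).min()
    if eigmin < -1e-10:
        raise ConfigurationError("random-effect covariance is not positive semi-definite")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    L = np.linalg.cholesky(cov + 1e-15 * np.eye(cov.shape[0]))
    z = rng.standard_normal((n, cov.shape[0]))
    out = z @ L.T
    out[:, np.asarray(spec.omega) == 0] = 0.0
    return out
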