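"""Covariate derivation formulas and forward-stepwise BIC covariate selection.

Renal function enters the final cefazolin model through creatinine
clearance; this module provides the Cockcroft-Gault and CKD-EPI (2009)
estimators, the Janmahasatian lean-body-weight formula, and the forward
stepwise search that adds one power-law (or sex-factor) covariate link at a
time as long as the Bayesian information criterion decreases.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core_model import CovariateSet, InputError

logger = logging.getLogger("cefpk")


def crcl_cockcroft_gault(cov: CovariateSet) -> float:
    """Cockcroft-Gault creatinine clearance in mL/min.

    ``(140 - age) * TBW / (0.814 * SCr[umol/L])``, times 0.85 for women.
    """
    if cov.age is None or cov.tbw is None:
        raise InputError("Cockcroft-Gault needs age, tbw and scr")
    scr = cov.scr_umol_l()
    if scr <= 0:
        raise InputError("serum creatinine must be positive")
    if cov.age >= 140:
        warnings.warn("age outside the plausible Cockcroft-Gault range", stacklevel=2)
        return 0.0
    value = (140.0 - cov.age) * cov.tbw / (0.814 * scr)
    if cov.get("sex") == 1.0:
        value *= 0.85
    return value


def crcl_ckdepi(cov: CovariateSet) -> float:
    """CKD-EPI (2009) estimated GFR in mL/min/1.73 m^2.

    ``141 * min(SCr/k, 1)^alpha * max(SCr/k, 1)^-1.209 * 0.993^age * 1.018[female]``
    with k = 0.7 (F) / 0.9 (M) and alpha = -0.329 (F) / -0.411 (M); SCr in mg/dL.
    """
    if cov.age is None or cov.sex is None:
        raise InputError("CKD-EPI needs age, sex and scr")
    scr = cov.scr_mg_dl()
    if scr <= 0:
        raise InputError("serum creatinine must be positive")
    female = cov.sex == "F"
    kappa = 0.7 if female else 0.9
    alpha = -0.329 if female else -0.411
    ratio = scr / kappa
    value = 141.0 * min(ratio, 1.0) ** alpha * max(ratio, 1.0) ** (-1.209) * 0.993**cov.age
    if female:
        value *= 1.018
    return value


def lean_body_weight(cov: CovariateSet) -> float:
    """Janmahasatian (2005) lean body weight in kg.

    male: 9270*TBW/(6680 + 216*BMI); female: 9270*TBW/(8780 + 244*BMI).
    """
    if cov.sex is None or cov.tbw is None or cov.bmi is None:
        raise InputError("lean body weight needs sex, tbw and bmi")
    if cov.bmi <= 0:
        raise InputError("bmi must be positive")
    if cov.sex == "M":
        return 9270.0 * cov.tbw / (6680.0 + 216.0 * cov.bmi)
    return 9270.0 * cov.tbw / (8780.0 + 244.0 * cov.bmi)


def derive_covariates(cov: CovariateSet) -> CovariateSet:
    """Fill crcl_cg, crcl_ckdepi and lbw in place (returns the same object)."""
    if cov.crcl_cg is None and cov.scr is not None and cov.age is not None and cov.tbw is not None:
        cov.crcl_cg = crcl_cockcroft_gault(cov)
    if cov.crcl_ckdepi is None and cov.scr is not None and cov.age is not None and cov.sex is not None:
        cov.crcl_ckdepi = crcl_ckdepi(cov)
    if cov.lbw is None and cov.sex is not None and cov.tbw is not None and cov.bmi is not None:
        cov.lbw = lean_body_weight(cov)
    return cov


# ---------------------------------------------------------------------------
# covariate links and stepwise selection
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CovariateLink:
    """One covariate-parameter link on the log scale.

    Continuous covariates use a power law centred on ``center``:
    ``param *= (cov/center)**coefficient``.  Sex uses a multiplicative
    factor for females: ``param *= exp(coefficient * I[female])``.

    The regressor feeding the linear log-scale model is therefore
    ``log(cov/center)`` for continuous covariates and the female indicator
    for sex.
    """

    parameter: str           # 'cl', 'vc', 'q', 'vp'
    covariate: str           # 'age', 'tbw', 'bmi', 'lbw', 'crcl_cg', 'crcl_ckdepi', 'sex'
    center: float = 1.0
    coefficient: float = 0.0

    def __post_init__(self):
        if self.center <= 0:
            raise InputError("centering constant must be positive")

    def regressor(self, cov: CovariateSet) -> float:
        if self.covariate == "sex":
            return cov.get("sex")
        value = cov.get(self.covariate)
        if value <= 0:
            raise InputError(f"covariate {self.covariate!r} must be positive")
        return float(np.log(value / self.center))

    def with_coefficient(self, value: float) -> "CovariateLink":
        return CovariateLink(self.parameter, self.covariate, self.center, float(value))

    def describe(self) -> str:
        return f"{self.covariate}->{self.parameter}"


#: the power-law centre of the final model's CrCL-on-CL link
CRCL_CENTER = 80.0

CANDIDATE_COVARIATES = ("age", "tbw", "bmi", "lbw", "crcl_cg", "crcl_ckdepi", "sex")


def default_candidates(data=None, parameters=("cl", "vc", "q", "vp"),
                       covariate_names=CANDIDATE_COVARIATES) -> list[CovariateLink]:
    """Candidate link set: each covariate on each parameter, one at a time.

    CrCL links are centred on 80; other continuous covariates on their
    cohort median when a dataset is supplied (1.0 otherwise, which only
    shifts the intercept).
    """
    centers = {}
    for name in covariate_names:
        if name == "sex":
            continue
        if name.startswith("crcl"):
            centers[name] = CRCL_CENTER
        elif data is not None:
            values = [c.get(name) for c in data.covariates.values()]
            centers[name] = float(np.median(values))
        else:
            centers[name] = 1.0
    out = []
    for p in parameters:
        for name in covariate_names:
            out.append(CovariateLink(p, name, centers.get(name, 1.0)))
    return out


@dataclass
class SelectionStep:
    description: str
    bic: float
    delta_bic: float
    omega: dict
    accepted: bool


@dataclass
class SelectionTrace:
    """Ordered record of a model-selection run; lowest-BIC model wins."""

    steps: list = field(default_factory=list)
    selected: object = None   # FitResult of the final model

    def add(self, description, bic, delta_bic, omega, accepted):
        self.steps.append(SelectionStep(description, float(bic), float(delta_bic), dict(omega), accepted))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "model": [s.description for s in self.steps],
                "BIC": [s.bic for s in self.steps],
                "dBIC": [s.delta_bic for s in self.steps],
                "accepted": [s.accepted for s in self.steps],
                **{
                    f"omega_{p}": [s.omega.get(p, np.nan) for s in self.steps]
                    for p in ("cl", "vc", "q", "vp")
                },
            }
        )

    @property
    def accepted_links(self) -> list:
        return [s.description for s in self.steps if s.accepted and "->" in s.description]


def forward_stepwise(base_fit, candidates, data, fit_fn,
                     max_steps: int | None = None) -> SelectionTrace:
    """Forward stepwise covariate search by BIC.

    Starting from ``base_fit`` (the converged covariate-free model), each
    round refits every remaining candidate link added singly and accepts the
    one with the largest BIC decrease; the search stops when no candidate
    lowers the BIC, or after ``max_steps`` accepted additions when given.
    ``fit_fn(data, links)`` must return a FitResult for the base model
    extended with ``links``.

    Candidates whose fit fails are skipped with a logged warning rather than
    aborting the search.
    """
    trace = SelectionTrace()
    trace.add("base", base_fit.bic, 0.0, base_fit.omega_dict(), accepted=True)
    current_bic = base_fit.bic
    current_links: list[CovariateLink] = []
    remaining = list(candidates)
    best_fit = base_fit
    while remaining and (max_steps is None or len(current_links) < max_steps):
        results = []
        for cand in remaining:
            try:
                fit = fit_fn(data, current_links + [cand])
            except Exception as exc:  # non-convergence must not kill the search
                logger.warning("CANDIDATE_SKIPPED link=%s reason=%s", cand.describe(), exc)
                continue
            results.append((cand, fit))
            trace.add(
                "+".join([c.describe() for c in current_links] + [cand.describe()]),
                fit.bic, fit.bic - current_bic, fit.omega_dict(), accepted=False,
            )
        if not results:
            break
        cand, fit = min(results, key=lambda r: r[1].bic)
        if fit.bic >= current_bic:
            break
        current_links.append(cand)
        current_bic = fit.bic
        best_fit = fit
        remaining = [c for c in remaining if c is not cand]
        # mark the accepted evaluation
        for s in trace.steps:
            if s.description == "+".join(c.describe() for c in current_links) and s.bic == fit.bic:
                s.accepted = True
    trace.selected = best_fit
    return trace


# ---------------------------------------------------------------------------
# reporting helpers (model-comparison bookkeeping)
# ---------------------------------------------------------------------------

def delta_bic(bic_without: float, bic_with: float) -> float:
    """BIC reduction achieved by the richer model, rounded to 2 decimals."""
    return round(bic_without - bic_with, 2)


def omega_reduction_percent(omega_base: float, omega_final: float) -> int:
    """Relative reduction of a between-subject SD, as an integer percent."""
    if omega_base <= 0:
        raise InputError("baseline omega must be positive")
    return int(round(100.0 * (omega_base - omega_final) / omega_base))
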