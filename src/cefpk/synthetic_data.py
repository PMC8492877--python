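"""Virtual cohorts emulating the THA cefazolin study design.

The generator reproduces the study's covariate structure (about 100 adults,
age 24-91 with mean 67, total body weight 48-123 kg with mean 76, ~29%
obese, CKD-EPI creatinine clearance 17-129 with mean ~83 mL/min/1.73 m^2),
its dosing protocol (2000 mg IV bolus at induction, 4000 mg when BMI > 35
AND TBW > 100 kg, redosing at 4 h for long surgeries), the five-sample
schedule (3 min, 20 min, end of surgery, 3 h, 8 h post-bolus), and the
proportional residual error with a 5 mg/L lower limit of quantification.

Serum creatinine is drawn (log-normally around the sex-specific CKD-EPI
knot) and creatinine clearance computed from it, so that SCr, sex, age and
CrCL stay mutually consistent; the SCr spread is calibrated so the cohort
CKD-EPI mean lands near 83 with roughly 9% of subjects below 60.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.optimize import brentq

from .core_model import ConfigurationError, CovariateSet, DoseEvent, observe, sample_etas
from .covariates import derive_covariates
from .data import EventDataset, build_records

logger = logging.getLogger("cefpk")


# ---------------------------------------------------------------------------
# design
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CohortDesign:
    """Study-design knobs of the virtual cohort; defaults are the study's."""

    n_subjects: int = 100
    seed: int | None = None
    # covariates
    age_mean: float = 67.0
    age_sd: float = 12.0
    age_range: tuple = (24.0, 91.0)
    female_fraction: float = 0.49
    tbw_mean: float = 76.0
    tbw_sd: float = 12.0
    tbw_range: tuple = (48.0, 123.0)
    height_mean_male: float = 1.74
    height_mean_female: float = 1.61
    height_sd: float = 0.065
    # SCr is a two-component log-normal mixture around the sex-specific
    # CKD-EPI knot kappa: SCr = kappa * exp(N(m, s)), with a majority
    # normal-renal-function component and a small chronic-kidney-disease
    # component supplying the low-clearance tail (the cohort's reported
    # renal strata: ~8% with CrCL 30-60 and ~1% below 30); draws are
    # resampled until the resulting CrCL falls inside crcl_range
    scr_logmean: float = -0.03
    scr_logsd: float = 0.18
    ckd_fraction: float = 0.07
    ckd_logmean: float = 0.60
    ckd_logsd: float = 0.30
    crcl_range: tuple = (17.0, 129.0)
    # surgery timing (h)
    duration_mean: float = 1.16
    duration_sd: float = 0.40
    duration_range: tuple = (0.49, 2.48)
    delay_mean: float = 0.85
    delay_sd: float = 0.40
    delay_range: tuple = (0.18, 2.23)
    # assay
    lloq: float = 5.0

    def __post_init__(self):
        if self.n_subjects < 1:
            raise ConfigurationError("need at least one subject")
        if self.lloq < 0:
            raise ConfigurationError("LLOQ must be non-negative")
        for lo, hi in (self.age_range, self.tbw_range, self.duration_range,
                       self.delay_range, self.crcl_range):
            if lo >= hi:
                raise ConfigurationError("truncation bounds must satisfy lo < hi")


def _truncnorm_exact_mean(target_mean, sd, lo, hi):
    """A scipy truncnorm whose *truncated* mean equals ``target_mean``.

    Truncation shifts the mean of a normal; this solves for the location
    parameter so the cohort-level moment checks hold without bias.
    """
    if not lo < target_mean < hi:
        raise ConfigurationError("target mean must lie inside the truncation bounds")

    def mean_err(loc):
        a, b = (lo - loc) / sd, (hi - loc) / sd
        return stats.truncnorm.mean(a, b, loc=loc, scale=sd) - target_mean

    loc = brentq(mean_err, lo, hi, xtol=1e-10)
    a, b = (lo - loc) / sd, (hi - loc) / sd
    return stats.truncnorm(a, b, loc=loc, scale=sd)


# ---------------------------------------------------------------------------
# cohort generation
# ---------------------------------------------------------------------------

def generate_cohort(design: CohortDesign = CohortDesign(), seed=None):
    """Draw covariate sets plus surgery timings for a virtual cohort.

    Returns ``(covariates, durations, delays)`` where ``durations`` is the
    surgery duration (incision to closure, h) and ``delays`` the
    injection-to-incision time (h).  Reproducible given the seed (argument
    overrides ``design.seed``).
    """
    rng = np.random.default_rng(design.seed if seed is None else seed)
    n = design.n_subjects
    age_dist = _truncnorm_exact_mean(design.age_mean, design.age_sd, *design.age_range)
    tbw_dist = _truncnorm_exact_mean(design.tbw_mean, design.tbw_sd, *design.tbw_range)
    dur_dist = _truncnorm_exact_mean(design.duration_mean, design.duration_sd,
                                     *design.duration_range)
    delay_dist = _truncnorm_exact_mean(design.delay_mean, design.delay_sd,
                                       *design.delay_range)

    ages = age_dist.ppf(rng.random(n))
    tbws = tbw_dist.ppf(rng.random(n))
    female = rng.random(n) < design.female_fraction
    h_mean = np.where(female, design.height_mean_female, design.height_mean_male)
    heights = h_mean + design.height_sd * rng.standard_normal(n)
    heights = np.clip(heights, 1.40, 2.05)
    durations = dur_dist.ppf(rng.random(n))
    delays = delay_dist.ppf(rng.random(n))

    covs = []
    for i in range(n):
        sex = "F" if female[i] else "M"
        kappa = 0.7 if female[i] else 0.9
        ckd = rng.random() < design.ckd_fraction
        m = design.ckd_logmean if ckd else design.scr_logmean
        s = design.ckd_logsd if ckd else design.scr_logsd
        cov = None
        for _ in range(1000):  # rejection: keep CrCL inside the study range
            scr_mgdl = kappa * np.exp(m + s * rng.standard_normal())
            cand = CovariateSet(age=float(ages[i]), sex=sex, tbw=float(tbws[i]),
                                height=float(heights[i]),
                                scr=float(scr_mgdl * 88.4), scr_unit="umol/L")
            derive_covariates(cand)
            if design.crcl_range[0] <= cand.crcl_ckdepi <= design.crcl_range[1]:
                cov = cand
                break
        if cov is None:
            raise ConfigurationError("could not draw a creatinine value inside the "
                                     "requested clearance range")
        covs.append(cov)
    return covs, durations, delays


# ---------------------------------------------------------------------------
# protocol
# ---------------------------------------------------------------------------

def protocol_doses(cov: CovariateSet, surgery_end: float) -> list:
    """Dose events under the study protocol.

    2000 mg at t=0 — 4000 mg when BMI > 35 kg/m^2 AND TBW > 100 kg — plus a
    redose at exactly t = 4 h (1000 mg, or 2000 mg for the doubled group)
    when surgery extends past 4 h after the injection.  ``surgery_end`` is
    the time of skin closure measured from the injection.
    """
    if surgery_end <= 0:
        raise ConfigurationError("surgery must end after the injection")
    doubled = (cov.bmi is not None and cov.bmi > 35.0
               and cov.tbw is not None and cov.tbw > 100.0)
    doses = [DoseEvent(time=0.0, amount=4000.0 if doubled else 2000.0)]
    if surgery_end > 4.0:
        doses.append(DoseEvent(time=4.0, amount=2000.0 if doubled else 1000.0))
    return doses


def sampling_times(injection_to_incision: float, surgery_duration: float) -> list:
    """The study's five nominal sampling times (h post-bolus), deduplicated.

    3 min, 20 min, end of surgery (injection-to-incision delay plus surgery
    duration), 3 h and 8 h; coincident times collapse to one sample.
    """
    if surgery_duration <= 0:
        raise ConfigurationError("surgery must end after incision")
    end_of_surgery = injection_to_incision + surgery_duration
    times = sorted({round(t, 6) for t in (0.05, 1.0 / 3.0, end_of_surgery, 3.0, 8.0)})
    return times


# ---------------------------------------------------------------------------
# forward simulation
# ---------------------------------------------------------------------------

def simulate_dataset(model, design: CohortDesign = CohortDesign(), seed=None,
                     cohort=None) -> EventDataset:
    """Simulate a full study dataset from a population model.

    Draws the cohort (unless one is supplied as ``(covs, durations, delays)``),
    applies the dosing protocol and sampling schedule, draws per-subject
    random effects and residual noise, truncates negative observations at 0
    (logged) and flags records below the LLOQ.
    """
    rng = np.random.default_rng(design.seed if seed is None else seed)
    if cohort is None:
        covs, durations, delays = generate_cohort(design, seed=rng.integers(2**31))
    else:
        covs, durations, delays = cohort
    etas = sample_etas(model.omega, len(covs), seed=rng.integers(2**31))
    frames = []
    n_negative = 0
    for i, cov in enumerate(covs):
        surgery_end = delays[i] + durations[i]
        doses = protocol_doses(cov, surgery_end)
        times = sampling_times(delays[i], durations[i])
        psi = model.mean_log_params([cov])[0] + etas[i]
        from .core_model import PKParameters, concentration

        params = PKParameters.from_array(np.exp(psi))
        f = np.array([concentration(params, doses, t) for t in times])
        eps = rng.standard_normal(len(times))
        obs = observe(f, model.error, eps)
        neg = obs < 0
        if neg.any():
            n_negative += int(neg.sum())
            obs = np.where(neg, 0.0, obs)
        blq = obs < design.lloq
        frames.append(build_records(i + 1, doses, times, obs, blq, cov))
    if n_negative:
        logger.warning("NEGATIVE_OBS_TRUNCATED n=%d", n_negative)
    df = pd.concat(frames, ignore_index=True)
    return EventDataset(df)
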