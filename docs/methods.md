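# Methods

## Model

`cefpk` implements a population pharmacokinetic analysis of cefazolin given
as an IV bolus for infection prophylaxis in total hip arthroplasty. The
structural model is a linear mammillary compartment model (1, 2 or 3
compartments) solved in closed form: a unit bolus into the central
compartment gives `c(t) = sum_k w_k exp(lambda_k t)`, with the exponents and
weights obtained from the classic biexponential formulas for two
compartments and from a batched eigendecomposition of the rate matrix for
three. Kinetics are linear, so multiple doses superpose exactly; doses are
instantaneous (the protocol is a direct bolus, not an infusion).
Parameterization is clearance/volume (CL, Vc, Q, Vp), converted internally
to rate constants; units are fixed at mg, L, h, mg/L.

The statistical model is nonlinear mixed-effects. Individual log-parameters
are Gaussian, `psi_i ~ N(X_i beta, Omega)`: log-normal parameters with
power-law covariate links (`param * (cov/center)^coef`) for continuous
covariates and a multiplicative factor for sex. The final model links
elimination clearance to CKD-EPI creatinine clearance centred on 80
mL/min/1.73 m². Omega is block-structured: a single CL–Vc covariance, all
other off-diagonals zero, fixed a priori rather than searched. Residual
error is `sd(obs|f) = a + b f`; the final model is purely proportional
(a = 0, b = 0.12).

Two interpretation decisions deserve note, since the source tabulation of
the reference estimates is ambiguous:

* The tabulated between-subject "variances" (e.g. 32, 57) are read as
  log-scale standard deviations × 100 (approximate CV%), i.e.
  omega_CL = 0.32. A literal variance of 32 on the log scale is
  implausible, and the SD reading reproduces the published dosing
  simulations (PTA table) within tolerance, which a variance reading does
  not.
* The CL–Vc correlation (0.83) is taken on the eta (log) scale.
* "Proportional residual variance (%) 12" is read as b = 0.12.

## Estimation (SAEM)

Maximum likelihood is computed by stochastic-approximation EM:

* **E-step**: per subject, a few Metropolis-within-Gibbs transitions on
  `psi_i` — one independence proposal from the prior `N(mu_i, Omega)`
  (whose acceptance ratio reduces to the observation likelihood) followed
  by random-walk proposals shaped by the current Omega Cholesky factor,
  with a per-subject scale adapted toward ~30% acceptance. All subjects
  move in parallel through vectorized likelihood evaluations.
* **Sufficient statistics**: stochastic approximation of the per-subject
  means `psi_bar_i` and the second-moment matrix, plus the residual-error
  moments; step size 1 during exploration, `(k - K1)^-0.7` during
  smoothing.
* **M-step**: the latent layer is linear-Gaussian, so the update is exact —
  GLS for beta (intercepts and covariate coefficients) under the current
  Omega, then the block-structured covariance MLE (the block-diagonal
  projection of the residual second moment; exact for this structure).
  The proportional (or additive) error parameter has a closed-form update;
  the combined model is maximized numerically against
  stochastic-approximated per-record moments, which is approximate but
  only used when a combined error model is requested.
* **Annealing**: during exploration the Omega diagonal and the error
  variance may shrink by at most 5% per iteration (floor
  `tau = 0.95` × previous value), preventing early collapse into a local
  mode.

Defaults are 300 exploration + 200 smoothing iterations with 5 kernel
transitions per iteration — enough that on the study design the parameter
traces are flat well before smoothing ends (a drift check over the last
smoothing half is recorded as a convergence flag). The run is reproducible
bit-for-bit given the seed.

Observations below the 5 mg/L quantification limit are excluded from the
likelihood with a logged count (about 0.5% of records under the study
design); a censored-likelihood treatment is out of scope.

The marginal log-likelihood is estimated by importance sampling with
per-subject Gaussian proposals centred at the empirical Bayes modes with
Laplace (inverse-Hessian) covariances; the Monte-Carlo SE is reported and
is ≈0.2 at the default 2000 samples on the study design. BIC is
`-2 logL + k ln(N)` with N = subjects by default (a configuration switch
allows observations). Empirical Bayes estimates are per-subject posterior
modes (BFGS from eta = 0); eta-shrinkage is `100 (1 - SD(EBE)/omega)`.

Relative standard errors come from the observed information obtained by
finite-differencing the importance-sampled log-likelihood under common
random numbers (fixed proposals and draws make the mapping smooth). This
replaces the stochastic-approximation Fisher matrix that pharmacometric
engines accumulate during the run; it is computed post hoc, is simpler to
validate, and on the study design gives RSEs of the same order as the
design supports (≈3% for CL, ≈7% for omega_CL, tens of percent for the
peripheral parameters).

Initial values use non-compartmental heuristics (dose/Cmax for the central
volume, terminal log-linear slope for elimination); SAEM with annealing is
robust to a factor of a few here.

## Covariate machinery and selection

Creatinine clearance comes from Cockcroft-Gault
(`(140-age) TBW / (0.814 SCr[umol/L])`, × 0.85 for women) or CKD-EPI 2009
(knot-spline in SCr with sex-specific kappa and alpha, `0.993^age`,
× 1.018 for women); serum creatinine carries an explicit unit (µmol/L or
mg/dL, 88.4 µmol/L per mg/dL). Lean body weight uses the Janmahasatian
(2005) formula — the field standard, since no formula is fixed by the
problem statement.

Covariate selection is forward stepwise by BIC: each round refits every
remaining candidate link added singly and accepts the largest BIC decrease,
stopping when no candidate lowers BIC (an optional `max_steps` truncates
the search). Candidates are one covariate on one parameter at a time;
continuous links centre on 80 for CrCL and the cohort median otherwise.
Failed candidate fits are skipped with a machine-parsable warning, never
silently dropped. Structural selection (1 vs 2 vs 3 compartments) fits each
candidate with shared settings and ranks by BIC.

## Synthetic cohorts

The generator emulates the THA study design so every downstream stage is
testable without clinical data:

* **Covariates**: age and total body weight are truncated normals whose
  *truncated* means are solved to hit the cohort targets (67 y in 24–91;
  76 kg in 48–123, SD 12); sex is ~51/49 M/F; height is drawn by sex
  (1.74/1.61 m, SD 0.065) and BMI derived, giving ~29% obese (BMI > 30)
  and ~7–8% BMI > 35. Serum creatinine is a two-component log-normal
  mixture around the sex-specific CKD-EPI knot — a majority
  normal-renal-function component and a 7% chronic-kidney-disease
  component — calibrated so the CKD-EPI clearance matches the cohort
  (mean ≈ 83–84, ≈9% below 60, ≈1% below 30, resampled into 17–129).
  Drawing SCr and computing CrCL keeps SCr, sex, age and CrCL mutually
  consistent. Only the marginals (plus the TBW→BMI-via-height link) are
  matched; the true joint covariate structure of a real cohort is not.
* **Protocol**: 2000 mg at t = 0, doubled to 4000 mg when BMI > 35 *and*
  TBW > 100 kg; a redose (1000 mg, or 2000 mg for the doubled group) at
  exactly 4 h post-injection when surgery extends past 4 h. Surgery
  duration (mean 1.16 h, 0.49–2.48) and injection-to-incision delay
  (mean 0.85 h, 0.18–2.23) are truncated normals with exact means.
* **Sampling**: 3 min (0.05 h), 20 min (1/3 h), end of surgery, 3 h and
  8 h post-bolus, deduplicated when coincident — ~500 concentrations per
  100 subjects, matching the study's 484.
* **Noise and censoring**: proportional error applied per record; negative
  draws truncated at zero with a logged count; records below the 5 mg/L
  LLOQ flagged.

What passing tests on these cohorts shows: the estimation and selection
machinery recovers the generating process under the study's design and
noise level. What it does not show: robustness to model misspecification,
assay drift, dropout, or covariate distributions unlike the cohort's.

## Diagnostics

* **pcVPC**: observations and 1000 simulated design replicates are rescaled
  by the bin-median population prediction
  (`pcY = Y * median(PRED_bin)/PRED`); quantile-based time bins (default
  6 — on the five-point schedule some bins merge, which is intended);
  the observed 5th/50th/95th percentiles are compared to 90% simulated
  confidence bands. With the correction disabled on a homogeneous design
  the result is a plain VPC, and the correction is provably a no-op when
  each bin holds a single sampling time.
* **NPDE**: per subject, observed and simulated vectors are decorrelated by
  the Cholesky factor of the simulated covariance; rank-based discrepancies
  (midpoint ties, clipped away from 0/1) map through the normal quantile.
  1000 simulations are needed for clean tail calibration — at a few
  hundred, rank discretization alone fails a KS test against N(0,1) in an
  appreciable fraction of replicates.
* **GOF**: PRED (eta = 0 at each subject's covariates), IPRED (EBEs), one
  row per usable observation; figures are renderings of the emitted tables,
  which are the testable surface.

## Dosing simulations

PTA simulations draw etas from the fitted Omega (CL–Vc correlation
included) and exclude residual error by default — the target of inference
is exposure, not assay replication; a flag includes it. 100 000 subjects
per scenario put the binomial SE below 0.16 percentage points, so the
reported PTA differences are model-driven, not sampling noise. The
efficacy threshold is MIC/fu (4/0.2 = 20 mg/L total); the toxicity summary
is the pointwise fraction above 360 mg/L and the per-subject trapezoid
duration above it, on a 0.05 h grid with the evaluation times (2.01 h skin
closure, 4 h) inserted exactly. The obese-subgroup regimen comparison
(4000+2000 vs 2000+1000 mg) uses individual-typical (eta = 0) curves at
five severe-obesity covariate profiles, matching how such subgroup
simulations are reported; an ensemble mode is available through the same
scenario machinery.

A note on one property often asserted loosely: the median of the simulated
ensemble equals the typical curve exactly only where concentration is a
single log-normal scaling (t → 0+, pure 1/Vc); with four correlated
log-normal parameters the ensemble median deviates from the eta = 0 curve
by up to ~4% mid-profile. Tests assert the exact property at t = 0+ and a
5% envelope elsewhere.

## Numerical choices and edge cases

* Closed-form kinetics agree with a stiff ODE integrator to <1e-6 relative
  error over random parameter draws (property-tested); mass balance holds
  to 1e-8 via quadrature.
* Degenerate inputs: empty dose lists give zero concentration; coincident
  sampling times deduplicate; subjects whose observations are all censored
  sit at the prior mode (eta = 0); omega = 0 components are held out of
  sampling; a non-PSD covariance is rejected at construction.
* The eigendecomposition path assumes the mammillary rate matrix's real
  spectrum (it is similar to a symmetric matrix); 2-compartment models use
  the explicit biexponential formulas instead.
* Proposal Hessians for the likelihood and RSEs are eigenvalue-clipped to
  stay positive definite; singular NPDE covariances are ridge-regularized
  with a warning.
* BIC's sample-size convention (subjects) follows mixed-model practice and
  is exposed as a switch, since the convention is genuinely ambiguous.

## Problem sizes used by the test suite

The suite favours many moderate fits over few large ones: recovery checks
use five replicate 100-subject cohorts at full SAEM settings; selection
consistency uses ten replicates each for structural and covariate search at
reduced settings (150+100 iterations), with the stepwise check truncated
after its first accepted step — the property under test. The
null-selection (BIC conservatism) check runs twenty replicates at full
settings, because short runs leave several logL units of estimation noise
between nested fits, which swamps the BIC penalty. PTA checks use
1e5 subjects per scenario. These sizes keep the whole suite and the
acceptance script fast on a single CPU while leaving every assertion's
sampling error well inside its tolerance.

## Known limitations

* No infusion dosing, saturable elimination, or absorption models — the
  protocol is IV bolus with linear kinetics.
* Below-LLOQ data are excluded, not modelled; no inter-occasion
  variability; no full Omega correlation search; FOCE/Laplace engines are
  not provided.
* The combined-error M-step is approximate (see above).
* Synthetic cohorts match marginal covariate distributions, not the joint
  distribution of a real population; conclusions about covariate-selection
  power transfer only to cohorts with comparable covariate information.
* Target-site (joint capsule) kinetics and PK/PD links to infection
  outcomes are out of scope.
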