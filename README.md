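# cefpk — population pharmacokinetics of prophylactic cefazolin in hip arthroplasty

Cefazolin is the standard antibiotic for surgical-site-infection prophylaxis
in total hip arthroplasty (THA). Whether its 2000 mg bolus should be adapted
to body weight or renal function is a live clinical question: the drug is
hydrophilic (volume of distribution barely grows with adiposity) but renally
cleared, so creatinine clearance — not weight — is the plausible driver of
exposure. `cefpk` is a tested, reusable implementation of the full
population-PK workflow for this problem, aimed at pharmacometricians and
methodologists: structural model selection, nonlinear mixed-effects
estimation by SAEM, covariate search, simulation-based diagnostics, and
Monte-Carlo dosing simulations, with a synthetic-cohort generator standing
in for clinical data.

## The model

Concentrations follow a mammillary 2-compartment model after IV bolus
dosing, embedded in a nonlinear mixed-effects framework:

    Obs_ij = F(t_ij, phi_i) + (a + b * F(t_ij, phi_i)) * eps_ij,   eps_ij ~ N(0, 1)

with log-normal between-subject variability and a power-law covariate link
of elimination clearance on CKD-EPI creatinine clearance, centred on the
cohort-typical 80 mL/min/1.73 m²:

    CL_i = theta_CL * (CrCL_i / 80)^theta_CrCL * exp(eta_CL,i),   eta ~ N(0, Omega)

Omega is diagonal except for a single CL–Vc covariance. The final model's
typical values are CL = 2.86 L/h, Vc = 5.2 L, Q = 10.9 L/h, Vp = 4.56 L,
theta_CrCL = 0.79, omegas (0.32, 0.57, 0.66, 0.10), corr(CL,Vc) = 0.83 and
a 12% proportional residual error.

Estimation is stochastic-approximation EM (SAEM): Metropolis-within-Gibbs
sampling of each subject's log-parameters, exact GLS/structured-covariance
M-steps, a simulated-annealing variance floor during exploration, and an
importance-sampled marginal likelihood (Laplace proposals at the empirical
Bayes modes) feeding the BIC used for structural and forward-stepwise
covariate selection. Diagnostics include the prediction-corrected VPC,
normalized prediction distribution errors (NPDE) and goodness-of-fit tables.

Dosing performance is summarized as probability of target attainment (PTA):
the fraction of simulated subjects whose total concentration stays at or
above 20 mg/L — a 4 mg/L MIC corrected for 80% protein binding — at skin
closure (2.01 h) and at the 4 h redosing landmark, plus the time spent above
the 360 mg/L neurotoxicity-associated cutoff.

## Worked example

```python
from cefpk import (CohortDesign, ModelSpec, SAEMSettings, saem_fit,
                   simulate_dataset, final_model)
from cefpk.covariates import CRCL_CENTER, CovariateLink
from cefpk.pta import crcl_profile_table

model = final_model()
data = simulate_dataset(model, CohortDesign(n_subjects=100), seed=1)

spec = ModelSpec(links=(CovariateLink("cl", "crcl_ckdepi", center=CRCL_CENTER),))
fit = saem_fit(data, spec, SAEMSettings(seed=2))
table = crcl_profile_table(fit.model, n_subjects=100_000, seed=3)
```

This simulates a 100-subject virtual THA cohort (5 samples each, 2000 mg
bolus protocol), refits it by SAEM, and evaluates PTA by renal function with
the refitted model. Output:

```
100 subjects, 500 concentrations, 2 below the 5 mg/L LLOQ
CL = 2.94 L/h, CrCL exponent = 0.86, Vc = 5.36 L
omega_CL = 0.33, corr(CL,Vc) = 0.87, b = 0.117
BIC = 4580.1, shrinkage CL = 1.2%
 crcl  pta_skin_closure_pct  pta_4h_pct
120.0                 100.0        93.3
 90.0                 100.0        99.6
 60.0                 100.0       100.0
 30.0                 100.0       100.0
```

The fit recovers the generating values (CL within 3%, the CrCL exponent
within its sampling error) with negligible eta-shrinkage, and the
simulations reproduce the clinical picture: a single 2000 mg bolus keeps
every renal-function profile above the 20 mg/L target through skin closure,
with attainment at 4 h degrading only for the fastest clearances.

The same workflow is available from the shell:

```bash
cefpk all --config run.yaml     # simulate -> fit -> select -> diagnose -> scenarios
```

where `run.yaml` holds the cohort design, SAEM settings and scenario grid;
each run directory gets a manifest with the seed and configuration hash.

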