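"""SAEM estimation, likelihood machinery, EBEs and shrinkage."""

import numpy as np
import pandas as pd
import pytest
from scipy.optimize import least_squares
from scipy.special import roots_hermitenorm

from cefpk import (
    CohortDesign,
    ErrorSpec,
    EventDataset,
    ModelSpec,
    PopulationModel,
    RandomEffectSpec,
    SAEMSettings,
    bic,
    empirical_bayes,
    log_likelihood,
    saem_fit,
    shrinkage,
    simulate_dataset,
)
from cefpk.estimation import predict_conc


class TestBIC:
    def test_direct_arithmetic(self):
        assert bic(-50.0, 3, 100) == pytest.approx(100 + 3 * np.log(100))
        assert bic(-50.0, 3, 100) == pytest.approx(113.8155, abs=5e-4)

    def test_zero_parameters(self):
        assert bic(-50.0, 0, 100) == 100.0


def _single_obs_dataset(y, t=1.0, dose=2000.0):
    df = pd.DataFrame({
        "ID": [1, 1], "TIME": [0.0, t], "AMT": [dose, np.nan],
        "DV": [np.nan, y], "EVID": [1, 0], "MDV": [1, 0], "BLQ": [0, 0],
    })
    return EventDataset(df)


class TestLogLikelihood:
    def test_closed_form_without_random_effects(self):
        """One subject, one observation, vanishing omega: the marginal
        likelihood collapses to the residual-error normal density."""
        model = PopulationModel(
            n_compartments=1, theta={"cl": 2.86, "vc": 5.2},
            omega=RandomEffectSpec(omega=(1e-5, 1e-5)),
            error=ErrorSpec(a=0.0, b=0.12),
        )
        ds = _single_obs_dataset(y=220.0)
        packed = ds.pack()
        f = predict_conc(model.mean_log_params([ds.covariates[1]]), packed, 1)[0, 0]
        sd = 0.12 * f
        expected = -0.5 * np.log(2 * np.pi) - np.log(sd) - 0.5 * ((220.0 - f) / sd) ** 2
        ll, se = log_likelihood(ds, model, n_samples=2000, seed=0)
        assert ll == pytest.approx(expected, abs=max(3 * se, 1e-3))

    def test_matches_quadrature_oracle(self):
        """Independent oracle: 2-D Gauss-Hermite quadrature over eta for a
        1-compartment model with two random effects."""
        model = PopulationModel(
            n_compartments=1, theta={"cl": 3.0, "vc": 6.0},
            omega=RandomEffectSpec(omega=(0.3, 0.4), corr_cl_vc=0.0),
            error=ErrorSpec(a=0.0, b=0.15),
        )
        df = pd.DataFrame({
            "ID": [1, 1, 1, 1], "TIME": [0.0, 0.5, 2.0, 6.0],
            "AMT": [2000.0, np.nan, np.nan, np.nan],
            "DV": [np.nan, 250.0, 150.0, 40.0],
            "EVID": [1, 0, 0, 0], "MDV": [1, 0, 0, 0], "BLQ": [0, 0, 0, 0],
        })
        ds = EventDataset(df)
        packed = ds.pack()
        mu = model.mean_log_params([ds.covariates[1]])[0]
        nodes, weights = roots_hermitenorm(80)
        m = packed.obs_mask[0]
        log_terms = []
        for i, zi in enumerate(nodes):
            for j, zj in enumerate(nodes):
                psi = mu + np.array([0.3 * zi, 0.4 * zj])
                f = predict_conc(psi[None, :], packed, 1)[0]
                sd = np.maximum(0.15 * f[m], 1e-300)
                with np.errstate(over="ignore"):
                    log_dens = np.sum(
                        np.clip(-0.5 * ((packed.y[0, m] - f[m]) / sd) ** 2, -1e300, 0)
                        - np.log(np.sqrt(2 * np.pi) * sd)
                    )
                log_terms.append(np.log(weights[i] * weights[j]) + log_dens)
        from scipy.special import logsumexp as lse

        oracle = lse(log_terms) - np.log(2 * np.pi)
        ll, se = log_likelihood(ds, model, n_samples=4000, seed=1)
        assert ll == pytest.approx(oracle, abs=max(3 * se, 5e-3))

    def test_mc_se_shrinks_with_sample_size(self, model, study_dataset):
        _, se1 = log_likelihood(study_dataset, model, n_samples=500, seed=2)
        _, se2 = log_likelihood(study_dataset, model, n_samples=2000, seed=2)
        assert se2 < se1
        assert se2 == pytest.approx(se1 / 2.0, rel=0.5)  # ~1/sqrt(4)

    def test_mc_se_small_at_10k_samples(self, model, study_dataset):
        _, se = log_likelihood(study_dataset, model, n_samples=10_000, seed=3)
        assert se < 0.5


class TestSAEMFit:
    def test_deterministic_given_seed(self, study_dataset):
        settings = SAEMSettings(n_exploration=40, n_smoothing=20, ll_samples=200, seed=9)
        fit1 = saem_fit(study_dataset, ModelSpec(), settings)
        fit2 = saem_fit(study_dataset, ModelSpec(), settings)
        pd.testing.assert_frame_equal(fit1.trace, fit2.trace)
        assert fit1.loglik == fit2.loglik

    def test_degenerate_variability_matches_pooled_nls(self, model):
        """With near-zero between-subject variability SAEM must agree with a
        pooled proportional-error nonlinear least-squares fit."""
        quiet = PopulationModel(
            n_compartments=2, theta=dict(model.theta), links=(),
            omega=RandomEffectSpec(omega=(1e-3, 1e-3, 1e-3, 1e-3)),
            error=ErrorSpec(a=0.0, b=0.05),
        )
        ds = simulate_dataset(quiet, CohortDesign(n_subjects=40), seed=21)
        packed = ds.pack()
        m = packed.obs_mask

        def residuals(log_theta):
            psi = np.broadcast_to(log_theta, (packed.n_subjects, 4))
            f = predict_conc(psi, packed, 2)
            return ((packed.y - f) / np.maximum(f, 1e-8))[m]

        nls = least_squares(residuals, np.log([3.0, 6.0, 8.0, 5.0]), method="lm")
        theta_nls = np.exp(nls.x)

        fit = saem_fit(ds, ModelSpec(),
                       SAEMSettings(n_exploration=200, n_smoothing=150,
                                    ll_samples=500, seed=22))
        theta_saem = fit.model.theta_vector()
        assert np.allclose(theta_saem, theta_nls, rtol=0.10)
        # CL and Vc variability collapses; Q is only weakly identified by
        # a five-sample design, so its omega decays more slowly
        om = fit.omega_dict()
        assert om["cl"] < 0.05 and om["vc"] < 0.05 and om["vp"] < 0.05
        assert om["q"] < 0.2

    def test_recovers_generating_values_single_replicate(self, model, study_dataset,
                                                         fast_settings):
        from cefpk.covariates import CRCL_CENTER, CovariateLink

        spec = ModelSpec(links=(CovariateLink("cl", "crcl_ckdepi", center=CRCL_CENTER),))
        fit = saem_fit(study_dataset, spec, fast_settings)
        assert fit.model.theta["cl"] == pytest.approx(2.86, rel=0.15)
        assert fit.model.links[0].coefficient == pytest.approx(0.79, abs=0.3)
        assert fit.model.error.b == pytest.approx(0.12, rel=0.25)
        assert fit.bic == pytest.approx(
            bic(fit.loglik, fit.n_params, fit.n_subjects), rel=1e-12
        )

    def test_blq_records_are_excluded_and_counted(self, model):
        ds = simulate_dataset(model, CohortDesign(n_subjects=50), seed=30)
        fit = saem_fit(ds, ModelSpec(),
                       SAEMSettings(n_exploration=30, n_smoothing=20,
                                    ll_samples=200, seed=31))
        assert fit.n_blq_excluded == ds.n_blq
        assert fit.n_obs == ds.n_observations - ds.n_blq


class TestCovariateSearch:
    def test_nested_model_never_loses_likelihood(self, model, study_dataset,
                                                 fast_settings):
        """Adding a covariate cannot decrease the maximized likelihood
        (within the Monte-Carlo noise of the estimator)."""
        from cefpk.covariates import CRCL_CENTER, CovariateLink

        base = saem_fit(study_dataset, ModelSpec(), fast_settings)
        rich = saem_fit(
            study_dataset,
            ModelSpec(links=(CovariateLink("cl", "crcl_ckdepi", center=CRCL_CENTER),)),
            fast_settings,
        )
        noise = 3 * np.hypot(base.loglik_se, rich.loglik_se) + 2.0
        assert rich.loglik >= base.loglik - noise

    def test_null_data_yields_empty_selection(self, model):
        """BIC conservatism: on data generated without covariate effects the
        forward search should usually accept nothing."""
        from cefpk import CohortDesign, forward_stepwise, simulate_dataset
        from cefpk.covariates import CovariateLink
        from cefpk.estimation import PopulationModel

        null_model = PopulationModel(
            n_compartments=2, theta=dict(model.theta), links=(),
            omega=model.omega, error=model.error,
        )
        # full-length fits: at short settings the base and candidate runs
        # differ by several logL units of estimation noise, which swamps the
        # BIC penalty and produces spurious acceptances
        empty = 0
        n_rep = 20
        for r in range(n_rep):
            ds = simulate_dataset(null_model, CohortDesign(n_subjects=100),
                                  seed=900 + r)
            run = SAEMSettings(seed=950 + r)
            base = saem_fit(ds, ModelSpec(), run)
            cands = [CovariateLink("cl", "age", center=67.0),
                     CovariateLink("cl", "tbw", center=76.0)]

            def fit_fn(d, links):
                return saem_fit(d, ModelSpec(links=tuple(links)), run)

            trace = forward_stepwise(base, cands, ds, fit_fn, max_steps=1)
            if not trace.accepted_links:
                empty += 1
        assert empty >= int(0.8 * n_rep)


class TestStandardErrors:
    def test_rse_magnitudes_match_design_information(self, model, study_dataset,
                                                     fast_settings):
        """RSEs from the observed information are of the order seen in
        comparable popPK analyses: a few percent for CL/Vc, tens of percent
        for the weakly identified peripheral parameters."""
        from cefpk.covariates import CRCL_CENTER, CovariateLink
        from cefpk.estimation import standard_errors

        spec = ModelSpec(links=(CovariateLink("cl", "crcl_ckdepi", center=CRCL_CENTER),))
        fit = saem_fit(study_dataset, spec, fast_settings)
        rse = standard_errors(study_dataset, fit, n_samples=300, seed=50)
        assert 1.0 < rse["cl"] < 15.0
        assert 1.0 < rse["vc"] < 20.0
        assert 3.0 < rse["beta_crcl_ckdepi->cl"] < 60.0
        assert 1.0 < rse["omega_cl"] < 30.0
        assert 0.5 < rse["error_b"] < 20.0


class TestCompareStructural:
    def test_one_compartment_data_selects_one_compartment(self):
        """Self-consistency: monoexponential data should not support the
        extra peripheral compartments."""
        from cefpk import CohortDesign, compare_structural, simulate_dataset
        from cefpk.estimation import PopulationModel

        one_cpt = PopulationModel(
            n_compartments=1, theta={"cl": 2.86, "vc": 9.8},
            omega=RandomEffectSpec(omega=(0.32, 0.45), corr_cl_vc=0.5),
            error=ErrorSpec(a=0.0, b=0.12),
        )
        ds = simulate_dataset(one_cpt, CohortDesign(n_subjects=100), seed=60)
        trace = compare_structural(
            ds, SAEMSettings(n_exploration=120, n_smoothing=80, ll_samples=800,
                             seed=61))
        assert trace.selected.spec.n_compartments == 1

    def test_identical_seeds_identical_trace(self, study_dataset):
        from cefpk import compare_structural

        settings = SAEMSettings(n_exploration=40, n_smoothing=25, ll_samples=200,
                                seed=62)
        a = compare_structural(study_dataset, settings, compartments=(1, 2))
        b = compare_structural(study_dataset, settings, compartments=(1, 2))
        pd.testing.assert_frame_equal(a.to_frame(), b.to_frame())


class TestEmpiricalBayes:
    def test_no_usable_observations_gives_prior_mode(self, model):
        df = pd.DataFrame({
            "ID": [1, 1], "TIME": [0.0, 1.0], "AMT": [2000.0, np.nan],
            "DV": [np.nan, 3.0], "EVID": [1, 0], "MDV": [1, 0], "BLQ": [0, 1],
            "CRCL_CKDEPI": [80.0, 80.0],
        })
        ds = EventDataset(df)
        ebes, failures = empirical_bayes(ds, model)
        assert np.all(ebes.to_numpy() == 0.0)
        assert not failures

    def test_mean_ebe_near_zero_under_true_model(self, model, study_dataset):
        ebes, _ = empirical_bayes(study_dataset, model)
        arr = ebes.to_numpy()
        for j, name in enumerate(model.param_names):
            se = arr[:, j].std(ddof=1) / np.sqrt(len(arr))
            assert abs(arr[:, j].mean()) < 3 * max(se, 1e-3), name

    def test_ebe_approaches_individual_nls_with_weak_prior(self):
        """With rich data and a diffuse prior the posterior mode tracks the
        subject's own nonlinear least-squares estimate."""
        rng = np.random.default_rng(33)
        true = {"cl": 3.2, "vc": 5.5}
        times = [0.1, 0.25, 0.5, 1.0, 2.0, 3.0, 5.0, 8.0]
        rows = [{"ID": 1, "TIME": 0.0, "AMT": 2000.0, "DV": np.nan,
                 "EVID": 1, "MDV": 1, "BLQ": 0}]
        for t in times:
            f = 2000.0 / true["vc"] * np.exp(-true["cl"] / true["vc"] * t)
            rows.append({"ID": 1, "TIME": t, "AMT": np.nan,
                         "DV": f * (1 + 0.05 * rng.standard_normal()),
                         "EVID": 0, "MDV": 0, "BLQ": 0})
        ds = EventDataset(pd.DataFrame(rows))
        packed = ds.pack()
        diffuse = PopulationModel(
            n_compartments=1, theta={"cl": 3.0, "vc": 6.0},
            omega=RandomEffectSpec(omega=(3.0, 3.0)),
            error=ErrorSpec(a=0.0, b=0.05),
        )
        ebes, _ = empirical_bayes(ds, diffuse)
        mu = diffuse.mean_log_params([ds.covariates[1]])[0]
        m = packed.obs_mask[0]

        def residuals(psi):
            f = predict_conc(psi[None, :], packed, 1)[0, m]
            return (packed.y[0, m] - f) / np.maximum(f, 1e-8)

        nls = least_squares(residuals, mu, method="lm")
        assert np.allclose(mu + ebes.to_numpy()[0], nls.x, atol=0.02)


class TestShrinkage:
    def test_no_shrinkage_when_ebe_sd_equals_omega(self):
        rng = np.random.default_rng(0)
        draws = rng.standard_normal(5000) * 0.3
        draws = (draws - draws.mean()) / draws.std(ddof=1) * 0.3
        ebes = pd.DataFrame({"eta_cl": draws})
        assert shrinkage(ebes, {"cl": 0.3})["cl"] == pytest.approx(0.0, abs=1e-9)

    def test_full_shrinkage_when_all_ebes_zero(self):
        ebes = pd.DataFrame({"eta_cl": np.zeros(10)})
        assert shrinkage(ebes, {"cl": 0.3})["cl"] == pytest.approx(100.0)

    def test_undefined_for_zero_omega(self):
        ebes = pd.DataFrame({"eta_cl": np.zeros(10)})
        assert np.isnan(shrinkage(ebes, {"cl": 0.0})["cl"])
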