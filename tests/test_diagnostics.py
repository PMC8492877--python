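"""pcVPC, NPDE and goodness-of-fit diagnostics."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from cefpk import (
    CohortDesign,
    ErrorSpec,
    EventDataset,
    PopulationModel,
    RandomEffectSpec,
    simulate_dataset,
)
from cefpk.diagnostics import gof_table, npde, pc_vpc


def _uniform_cohort_dataset(model, n=40, seed=0):
    """Every subject identical: same covariates, same doses, same times."""
    from cefpk.core_model import CovariateSet, DoseEvent, concentration, PKParameters
    from cefpk.core_model import sample_etas, observe
    from cefpk.data import build_records

    rng = np.random.default_rng(seed)
    cov = CovariateSet(age=67, sex="M", tbw=76, height=1.74, scr=80.0,
                       crcl_ckdepi=80.0, crcl_cg=80.0)
    times = [0.05, 1.0 / 3.0, 2.0, 3.0, 8.0]
    doses = [DoseEvent(0.0, 2000.0)]
    etas = sample_etas(model.omega, n, seed=rng.integers(2**31))
    frames = []
    for i in range(n):
        psi = model.mean_log_params([cov])[0] + etas[i]
        params = PKParameters.from_array(np.exp(psi))
        f = np.array([concentration(params, doses, t) for t in times])
        obs = observe(f, model.error, rng.standard_normal(len(times)))
        frames.append(build_records(i + 1, doses, times, np.maximum(obs, 0.0),
                                    obs < 0, cov))
    return EventDataset(pd.concat(frames, ignore_index=True))


class TestPcVPC:
    def test_correction_is_identity_for_uniform_design(self, model):
        """With identical subjects PRED is constant within bins, so the
        prediction correction must change nothing."""
        ds = _uniform_cohort_dataset(model, n=40, seed=1)
        # one bin per distinct sampling time so PRED is constant within bins
        with_corr = pc_vpc(ds, model, n_simulations=200, bins=5, seed=5)
        without = pc_vpc(ds, model, n_simulations=200, bins=5, seed=5,
                         prediction_corrected=False)
        pd.testing.assert_frame_equal(with_corr.table, without.table)

    def test_self_consistency_coverage(self, model, study_dataset):
        """Data simulated from the model itself: observed percentiles sit
        inside the 90% simulated bands in nearly every bin."""
        result = pc_vpc(study_dataset, model, n_simulations=500, seed=6)
        t = result.table
        inside = ((t["observed"] >= t["sim_lo"]) & (t["observed"] <= t["sim_hi"]))
        assert inside.mean() >= 0.9

    def test_default_simulation_count(self, model, study_dataset):
        import inspect

        assert inspect.signature(pc_vpc).parameters["n_simulations"].default == 1000

    def test_percentiles_ordered(self, model, study_dataset):
        t = pc_vpc(study_dataset, model, n_simulations=200, seed=7).table
        wide = t.pivot(index="bin", columns="percentile", values="observed")
        assert (wide[5.0] <= wide[50.0]).all() and (wide[50.0] <= wide[95.0]).all()

    def test_reproducible_given_seed(self, model, study_dataset):
        a = pc_vpc(study_dataset, model, n_simulations=150, seed=8).table
        b = pc_vpc(study_dataset, model, n_simulations=150, seed=8).table
        pd.testing.assert_frame_equal(a, b)


class TestNPDE:
    def test_null_calibration(self, model, study_dataset):
        """Under the true model NPDE are approximately standard normal."""
        values = npde(study_dataset, model, n_simulations=1000, seed=9)["NPDE"]
        n = len(values)
        assert abs(values.mean()) < 3.0 / np.sqrt(n)
        var_se = np.sqrt(2.0 / (n - 1))
        assert abs(values.var(ddof=1) - 1.0) < 3 * var_se

    def test_single_observation_reduces_to_marginal_quantile(self, model):
        ds = _uniform_cohort_dataset(model, n=10, seed=2)
        keep = ds.df[(ds.df["EVID"] == 1) | (ds.df["TIME"] == 3.0)]
        ds1 = EventDataset(keep.reset_index(drop=True))
        values = npde(ds1, model, n_simulations=1000, seed=10)
        # manual marginal check for the first subject
        from cefpk.diagnostics import _simulate_observations

        packed = ds1.pack()
        covs = [ds1.covariates[sid] for sid in packed.ids]
        mu = model.mean_log_params(covs)
        sims = _simulate_observations(packed, model, mu, 1000,
                                      np.random.default_rng(10))
        y = packed.y[0, packed.obs_mask[0]][0]
        sim0 = sims[0][:, packed.obs_mask[0]][:, 0]
        expected = stats.norm.ppf(np.clip((sim0 < y).mean() + 0.5 * (sim0 == y).mean(),
                                          1e-4, 1 - 1e-4))
        assert values["NPDE"].iloc[0] == pytest.approx(expected, abs=1e-9)

    def test_detects_misspecified_clearance(self, model, study_dataset):
        """Halving CL inflates predictions; the NPDE mean shifts far from 0."""
        wrong = PopulationModel(
            n_compartments=2,
            theta={**model.theta, "cl": model.theta["cl"] / 2.0},
            links=model.links,
            omega=model.omega,
            error=model.error,
        )
        values = npde(study_dataset, wrong, n_simulations=600, seed=11)["NPDE"]
        # mean NPDE collapses far below zero: an order of magnitude beyond
        # the null sampling error of the mean
        assert abs(values.mean()) > 0.8
        assert abs(values.mean()) > 10.0 / np.sqrt(len(values))

    def test_distribution_passes_ks_against_standard_normal(self, model):
        """Replicate synthetic datasets: the NPDE sample is compatible with
        N(0,1) at alpha=0.01 in nearly all replicates."""
        passes = 0
        n_rep = 20
        for r in range(n_rep):
            ds = simulate_dataset(model, CohortDesign(n_subjects=50), seed=500 + r)
            values = npde(ds, model, n_simulations=1000, seed=600 + r)["NPDE"]
            if stats.kstest(values, "norm").pvalue > 0.01:
                passes += 1
        assert passes >= int(0.95 * n_rep)


class TestGOF:
    def test_pred_equals_ipred_without_random_effects(self, model):
        quiet = PopulationModel(
            n_compartments=2, theta=dict(model.theta), links=model.links,
            omega=RandomEffectSpec(omega=(1e-8, 1e-8, 1e-8, 1e-8)),
            error=ErrorSpec(a=0.0, b=0.12),
        )
        ds = simulate_dataset(quiet, CohortDesign(n_subjects=10), seed=12)
        table = gof_table(ds, quiet)
        assert np.allclose(table["PRED"], table["IPRED"], rtol=1e-4)

    def test_error_free_observations_equal_ipred_at_true_etas(self, model):
        """Without residual noise the individual prediction at the true etas
        reproduces the observations exactly."""
        from cefpk.core_model import (PKParameters, concentration, sample_etas,
                                      DoseEvent)
        from cefpk.data import build_records
        from cefpk.synthetic_data import generate_cohort

        covs, dur, dly = generate_cohort(CohortDesign(n_subjects=8), seed=13)
        etas = sample_etas(model.omega, 8, seed=14)
        frames = []
        for i, cov in enumerate(covs):
            doses = [DoseEvent(0.0, 2000.0)]
            times = [0.05, 0.5, 2.0, 3.0, 8.0]
            psi = model.mean_log_params([cov])[0] + etas[i]
            f = [concentration(PKParameters.from_array(np.exp(psi)), doses, t)
                 for t in times]
            frames.append(build_records(i + 1, doses, times, f, [False] * 5, cov))
        ds = EventDataset(pd.concat(frames, ignore_index=True))
        true_etas = pd.DataFrame(etas, index=ds.subject_ids,
                                 columns=[f"eta_{p}" for p in model.param_names])
        table = gof_table(ds, model, ebes=true_etas)
        assert np.allclose(table["IPRED"], table["DV"], rtol=1e-9)

    def test_calibration_slope_near_unity(self, model, study_dataset):
        table = gof_table(study_dataset, model)
        slope = np.polyfit(table["IPRED"], table["DV"], 1)[0]
        assert 0.9 <= slope <= 1.1
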