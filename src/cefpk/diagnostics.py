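"""Model-evaluation machinery: prediction-corrected VPC, NPDE, goodness of fit.

All diagnostics are simulation-based and reproducible given a seed.  The
acceptance surface is the emitted tables; figures are a thin rendering on
top of them.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .core_model import InputError
from .data import EventDataset, Packed
from .estimation import PopulationModel, empirical_bayes, predict_conc

logger = logging.getLogger("cefpk")


def _simulate_observations(packed: Packed, model: PopulationModel, mu, n_simulations,
                           rng) -> np.ndarray:
    """Simulated replicate observations (N, n_sim, J) under the fitted model."""
    from .core_model import sample_etas

    N, J = packed.y.shape
    etas = sample_etas(model.omega, N * n_simulations, seed=rng.integers(2**31))
    psi = mu[:, None, :] + etas.reshape(N, n_simulations, -1)
    f = predict_conc(psi, packed, model.n_compartments)
    eps = rng.standard_normal(f.shape)
    sim = f + (model.error.a + model.error.b * f) * eps
    return np.maximum(sim, 0.0)


# ---------------------------------------------------------------------------
# prediction-corrected VPC
# ---------------------------------------------------------------------------

@dataclass
class VPCResult:
    """Binned percentiles of prediction-corrected observations with simulated bands."""

    table: pd.DataFrame   # one row per (bin, percentile)
    n_simulations: int
    percentiles: tuple = (5.0, 50.0, 95.0)

    def to_frame(self) -> pd.DataFrame:
        return self.table


def pc_vpc(data: EventDataset, model: PopulationModel, n_simulations: int = 1000,
           bins: int = 6, seed=None, prediction_corrected: bool = True,
           ci_level: float = 0.90) -> VPCResult:
    """Prediction-corrected visual predictive check.

    Observations (and each of ``n_simulations`` simulated replicates of the
    design) are rescaled by the bin-median population prediction,
    ``pcY_ij = Y_ij * median(PRED_bin) / PRED_ij``, removing dose and
    covariate heterogeneity; per time bin the observed 5th/50th/95th
    percentiles are compared with the simulated confidence band of the same
    percentile.  Records with PRED=0 are excluded with a warning; empty
    bins merge into their neighbour by construction of quantile binning.
    """
    if n_simulations < 100:
        raise InputError("need at least 100 simulated replicates")
    rng = np.random.default_rng(seed)
    packed = data.pack()
    covs = [data.covariates[sid] for sid in packed.ids]
    mu = model.mean_log_params(covs)
    pred = predict_conc(mu, packed, model.n_compartments)   # population prediction

    mask = packed.obs_mask.copy()
    bad = mask & (pred <= 0)
    if bad.any():
        logger.warning("VPC_PRED_ZERO n=%d records excluded", int(bad.sum()))
        mask &= pred > 0

    t = packed.t_obs[mask]
    y = packed.y[mask]
    p = pred[mask]
    sims = _simulate_observations(packed, model, mu, n_simulations, rng)
    s = sims.transpose(0, 2, 1)[mask]                       # (n_records, n_sim)

    # quantile time bins (unique edges => empty bins merge automatically)
    edges = np.unique(np.quantile(t, np.linspace(0, 1, bins + 1)))
    idx = np.clip(np.searchsorted(edges, t, side="right") - 1, 0, len(edges) - 2)

    pcts = (5.0, 50.0, 95.0)
    alpha = (1.0 - ci_level) / 2.0
    rows = []
    for b in range(len(edges) - 1):
        in_bin = idx == b
        if not in_bin.any():
            continue
        med_pred = np.median(p[in_bin])
        corr = med_pred / p[in_bin] if prediction_corrected else np.ones(in_bin.sum())
        y_pc = y[in_bin] * corr
        s_pc = s[in_bin] * np.asarray(corr)[:, None]
        for q in pcts:
            obs_q = np.percentile(y_pc, q)
            sim_q = np.percentile(s_pc, q, axis=0)          # per replicate
            rows.append({
                "bin": b, "t_lo": edges[b], "t_hi": edges[b + 1],
                "t_mid": float(np.median(t[in_bin])), "n": int(in_bin.sum()),
                "percentile": q, "observed": float(obs_q),
                "sim_lo": float(np.quantile(sim_q, alpha)),
                "sim_med": float(np.quantile(sim_q, 0.5)),
                "sim_hi": float(np.quantile(sim_q, 1.0 - alpha)),
            })
    table = pd.DataFrame(rows)
    return VPCResult(table=table, n_simulations=n_simulations, percentiles=pcts)


# ---------------------------------------------------------------------------
# NPDE
# ---------------------------------------------------------------------------

def npde(data: EventDataset, model: PopulationModel, n_simulations: int = 1000,
         seed=None) -> pd.DataFrame:
    """Normalized prediction distribution errors.

    Per subject the observed vector and each simulated replicate are
    decorrelated with the Cholesky factor of the simulated covariance;
    rank-based prediction discrepancies (midpoint tie convention) are then
    mapped through the standard normal quantile.  Under the true model the
    NPDE are approximately iid N(0, 1).
    """
    if n_simulations < 500:
        raise InputError("need at least 500 simulated replicates")
    rng = np.random.default_rng(seed)
    packed = data.pack()
    covs = [data.covariates[sid] for sid in packed.ids]
    mu = model.mean_log_params(covs)
    sims = _simulate_observations(packed, model, mu, n_simulations, rng)

    rows = []
    for i in range(packed.n_subjects):
        m = packed.obs_mask[i]
        if not m.any():
            continue
        y_i = packed.y[i, m]                 # (J_i,)
        s_i = sims[i][:, m]                  # (n_sim, J_i)
        mean_i = s_i.mean(axis=0)
        cov_i = np.atleast_2d(np.cov(s_i, rowvar=False))
        try:
            L = np.linalg.cholesky(cov_i)
        except np.linalg.LinAlgError:
            logger.warning("NPDE_SINGULAR_COV subject=%s ridge-regularized", packed.ids[i])
            ridge = 1e-8 * np.trace(cov_i) / cov_i.shape[0] + 1e-12
            L = np.linalg.cholesky(cov_i + ridge * np.eye(cov_i.shape[0]))
        y_dec = np.linalg.solve(L, y_i - mean_i)
        s_dec = np.linalg.solve(L, (s_i - mean_i).T).T
        # midpoint rank: P(sim < obs) + 0.5 P(sim == obs)
        pd_i = (s_dec < y_dec).mean(axis=0) + 0.5 * (s_dec == y_dec).mean(axis=0)
        pd_i = np.clip(pd_i, 1.0 / (2 * n_simulations), 1.0 - 1.0 / (2 * n_simulations))
        values = stats.norm.ppf(pd_i)
        for tt, yy, v in zip(packed.t_obs[i, m], y_i, values):
            rows.append({"ID": packed.ids[i], "TIME": float(tt), "DV": float(yy),
                         "NPDE": float(v)})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# goodness of fit
# ---------------------------------------------------------------------------

def gof_table(data: EventDataset, model: PopulationModel, ebes: pd.DataFrame = None,
              npde_values: pd.DataFrame = None) -> pd.DataFrame:
    """Observed vs population (PRED) and individual (IPRED) predictions.

    PRED sets every random effect to zero (typical subject at the
    individual's covariates); IPRED plugs in the empirical Bayes estimates.
    One row per usable (non-BLQ) observation.
    """
    packed = data.pack()
    covs = [data.covariates[sid] for sid in packed.ids]
    mu = model.mean_log_params(covs)
    pred = predict_conc(mu, packed, model.n_compartments)
    if ebes is None:
        ebes, _ = empirical_bayes(data, model, packed=packed)
    ipred = predict_conc(mu + ebes.to_numpy(), packed, model.n_compartments)
    rows = []
    for i in range(packed.n_subjects):
        m = packed.obs_mask[i]
        for tt, yy, pp, ii in zip(packed.t_obs[i, m], packed.y[i, m],
                                  pred[i, m], ipred[i, m]):
            rows.append({"ID": packed.ids[i], "TIME": float(tt), "DV": float(yy),
                         "PRED": float(pp), "IPRED": float(ii)})
    table = pd.DataFrame(rows)
    if npde_values is not None:
        table = table.merge(npde_values[["ID", "TIME", "NPDE"]], on=["ID", "TIME"],
                            how="left")
    return table


# ---------------------------------------------------------------------------
# figures (tables first; images are renderings of them)
# ---------------------------------------------------------------------------

def plot_vpc(result: VPCResult, path):
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(7, 5))
    colors = {5.0: "tab:blue", 50.0: "tab:orange", 95.0: "tab:blue"}
    for q, sub in result.table.groupby("percentile"):
        sub = sub.sort_values("t_mid")
        ax.fill_between(sub["t_mid"], sub["sim_lo"], sub["sim_hi"],
                        alpha=0.25, color=colors.get(q, "grey"))
        ax.plot(sub["t_mid"], sub["sim_med"], "--", color=colors.get(q, "grey"), lw=1)
        ax.plot(sub["t_mid"], sub["observed"], "o-", color="black", ms=4, lw=1.2)
    ax.set_xlabel("time after first bolus (h)")
    ax.set_ylabel("prediction-corrected concentration (mg/L)")
    ax.set_yscale("log")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def plot_gof(table: pd.DataFrame, path):
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    n = 3 if "NPDE" in table.columns else 2
    fig, axes = plt.subplots(1, n, figsize=(4 * n, 4))
    for ax, col in zip(axes[:2], ("PRED", "IPRED")):
        ax.plot(table[col], table["DV"], "o", ms=3, alpha=0.5)
        lim = [0, max(table[col].max(), table["DV"].max()) * 1.05]
        ax.plot(lim, lim, "k-", lw=1)
        ax.set_xlabel(f"{col} (mg/L)")
        ax.set_ylabel("observed (mg/L)")
    if n == 3:
        axes[2].plot(table["TIME"], table["NPDE"], "o", ms=3, alpha=0.5)
        axes[2].axhline(0, color="k", lw=1)
        axes[2].set_xlabel("time (h)")
        axes[2].set_ylabel("NPDE")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
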