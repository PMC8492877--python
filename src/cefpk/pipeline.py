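"""End-to-end analysis pipeline with a reproducibility manifest.

Stages run in order — simulate/load, structural comparison, base fit,
covariate selection, diagnostics, dosing scenarios — each writing its
outputs and a completion marker into the run directory.  A re-run resumes
past the simulate stage by reloading the already-written dataset (so the
downstream stages see identical data), and a stage failure stops all
downstream stages.  The manifest records package version, seed,
configuration hash and stage timings.
"""

from __future__ import annotations

import json
import logging
import time
from pathlib import Path

import numpy as np

from .covariates import default_candidates, forward_stepwise
from .diagnostics import gof_table, npde, pc_vpc, plot_gof, plot_vpc
from .estimation import ModelSpec, SAEMSettings, compare_structural, saem_fit
from .io import RunConfig, read_dataset, write_dataset
from .pta import crcl_profile_table
from .reference import final_model
from .synthetic_data import simulate_dataset
from . import __version__

logger = logging.getLogger("cefpk")


def _setup_logging(run_dir: Path):
    handler = logging.FileHandler(run_dir / "run.log")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    logger.addHandler(handler)
    logger.setLevel(logging.INFO)
    return handler


def run_pipeline(config: RunConfig) -> Path:
    """Execute the configured stages; returns the run directory.

    Every output in the directory traces back to the manifest's seed and
    configuration hash.
    """
    run_dir = Path(config.output_dir)
    run_dir.mkdir(parents=True, exist_ok=True)
    handler = _setup_logging(run_dir)
    manifest = {
        "package": "cefpk",
        "version": __version__,
        "seed": config.seed,
        "config_hash": config.config_hash(),
        "stages": {},
    }
    rng = np.random.default_rng(config.seed)
    stage_seeds = {s: int(rng.integers(2**31)) for s in
                   ("simulate", "fit", "select", "diagnose", "scenarios")}
    t_stage = time.time()

    def finish(stage):
        nonlocal t_stage
        (run_dir / f".{stage}.done").touch()
        manifest["stages"][stage] = {"seconds": round(time.time() - t_stage, 2),
                                     "seed": stage_seeds.get(stage)}
        logger.info("STAGE_DONE stage=%s seconds=%.1f", stage, time.time() - t_stage)
        t_stage = time.time()

    try:
        # ---- data: load, or simulate from the published final model
        if config.dataset is not None:
            data = read_dataset(config.dataset)
        elif (run_dir / ".simulate.done").exists() and (run_dir / "dataset.csv").exists():
            logger.info("STAGE_RESUMED stage=simulate (reusing dataset.csv)")
            data = read_dataset(run_dir / "dataset.csv")
        else:
            data = simulate_dataset(final_model(), config.design,
                                    seed=stage_seeds["simulate"])
            write_dataset(data, run_dir / "dataset.csv")
        manifest.update(n_subjects=data.n_subjects, n_observations=data.n_observations,
                        n_blq=data.n_blq)
        if "simulate" in config.stages:
            finish("simulate")

        settings = SAEMSettings(**{**config.saem.__dict__, "seed": stage_seeds["fit"]})

        # ---- structural comparison + base fit
        base_fit = None
        base_spec = ModelSpec(n_compartments=config.n_compartments,
                              error_model=config.error_model)
        if "fit" in config.stages:
            if config.structural_search:
                trace = compare_structural(data, settings)
                trace.to_frame().to_csv(run_dir / "structural_comparison.csv",
                                        index=False)
                base_fit = trace.selected
                base_spec = ModelSpec(n_compartments=base_fit.spec.n_compartments,
                                      error_model=config.error_model)
            else:
                base_fit = saem_fit(data, base_spec, settings)
            base_fit.summary().to_csv(run_dir / "fit_base.csv", index=False)
            finish("fit")

        # ---- covariate selection
        final_fit = base_fit
        if config.covariate_search and base_fit is not None and "select" in config.stages:
            cands = default_candidates(data, parameters=config.candidate_parameters,
                                       covariate_names=config.candidate_covariates)
            sel_settings = SAEMSettings(**{**settings.__dict__,
                                           "seed": stage_seeds["select"]})

            def fit_fn(d, links):
                spec = ModelSpec(n_compartments=base_spec.n_compartments,
                                 links=tuple(links), error_model=config.error_model)
                return saem_fit(d, spec, sel_settings)

            sel = forward_stepwise(base_fit, cands, data, fit_fn)
            sel.to_frame().to_csv(run_dir / "covariate_selection.csv", index=False)
            final_fit = sel.selected
            final_fit.summary().to_csv(run_dir / "fit_final.csv", index=False)
            finish("select")

        # ---- diagnostics
        if final_fit is not None and "diagnose" in config.stages:
            model = final_fit.model
            vpc = pc_vpc(data, model, n_simulations=config.diagnostics_simulations,
                         bins=config.vpc_bins, seed=stage_seeds["diagnose"])
            vpc.table.to_csv(run_dir / "vpc.csv", index=False)
            plot_vpc(vpc, run_dir / "vpc.png")
            npde_values = npde(data, model,
                               n_simulations=max(config.diagnostics_simulations, 500),
                               seed=stage_seeds["diagnose"] + 1)
            gof = gof_table(data, model, ebes=final_fit.ebes, npde_values=npde_values)
            gof.to_csv(run_dir / "gof.csv", index=False)
            plot_gof(gof, run_dir / "gof.png")
            finish("diagnose")

        # ---- dosing scenarios
        if "scenarios" in config.stages:
            model = final_fit.model if final_fit is not None else final_model()
            table = crcl_profile_table(model, crcl_values=config.scenario_crcl,
                                       n_subjects=config.scenario_n_subjects,
                                       seed=stage_seeds["scenarios"])
            table.to_csv(run_dir / "pta_by_crcl.csv", index=False)
            finish("scenarios")
    except Exception:
        logger.exception("PIPELINE_FAILED")
        raise
    finally:
        with open(run_dir / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=2)
        logger.removeHandler(handler)
        handler.close()
    return run_dir
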