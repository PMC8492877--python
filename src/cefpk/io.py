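"""Dataset and configuration I/O.

Datasets travel as NONMEM-convention CSV (ID, TIME, AMT, DV, EVID, MDV,
BLQ, plus covariate columns, time-constant per subject).  Run
configuration lives in a single YAML file with a strict schema: unknown
keys are rejected by name.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from .data import REQUIRED_COLUMNS, DatasetError, EventDataset
from .estimation import SAEMSettings
from .synthetic_data import CohortDesign

logger = logging.getLogger("cefpk")


def read_dataset(path) -> EventDataset:
    """Read and validate a NONMEM-convention CSV event dataset."""
    path = Path(path)
    if not path.exists():
        raise DatasetError(f"dataset file not found: {path}")
    df = pd.read_csv(path)
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise DatasetError(f"missing required columns in {path.name}: {missing}")
    ds = EventDataset(df)
    logger.info("DATASET_READ path=%s rows=%d subjects=%d observations=%d",
                path, len(df), ds.n_subjects, ds.n_observations)
    return ds


def write_dataset(ds: EventDataset, path) -> None:
    """Write an event dataset to CSV (round-trips through read_dataset)."""
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    ds.df.to_csv(path, index=False)


# ---------------------------------------------------------------------------
# run configuration
# ---------------------------------------------------------------------------

class ConfigError(ValueError):
    """Raised when a run configuration is malformed."""


@dataclass
class RunConfig:
    """Everything needed to reproduce a run from a single YAML file."""

    output_dir: str = "cefpk_run"
    seed: int = 12345
    dataset: str | None = None                     # path; exclusive with design
    design: CohortDesign | None = None             # synthetic-cohort block
    n_compartments: int = 2
    covariate_search: bool = True
    structural_search: bool = True
    error_model: str = "proportional"
    candidate_parameters: tuple = ("cl", "vc")
    candidate_covariates: tuple = ("age", "tbw", "lbw", "crcl_ckdepi", "sex")
    saem: SAEMSettings = field(default_factory=SAEMSettings)
    diagnostics_simulations: int = 1000
    vpc_bins: int = 6
    scenario_crcl: tuple = (120.0, 90.0, 60.0, 30.0)
    scenario_n_subjects: int = 100_000
    stages: tuple = ("simulate", "fit", "select", "diagnose", "scenarios")

    def __post_init__(self):
        if (self.dataset is None) == (self.design is None):
            raise ConfigError("exactly one data source required: 'dataset' or 'design'")

    def config_hash(self) -> str:
        payload = asdict(self)
        return hashlib.sha256(json.dumps(payload, sort_keys=True, default=str)
                              .encode()).hexdigest()[:16]


_TOP_KEYS = {
    "output_dir", "seed", "dataset", "design", "n_compartments", "covariate_search",
    "structural_search", "error_model", "candidate_parameters",
    "candidate_covariates", "saem", "diagnostics_simulations", "vpc_bins",
    "scenario_crcl", "scenario_n_subjects", "stages",
}


def load_config(path) -> RunConfig:
    """Parse a YAML run configuration, rejecting unknown keys by name."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    if not isinstance(raw, dict):
        raise ConfigError("configuration must be a YAML mapping")
    unknown = set(raw) - _TOP_KEYS
    if unknown:
        raise ConfigError(f"unknown configuration key(s): {sorted(unknown)}")
    kwargs = dict(raw)
    if "design" in kwargs and kwargs["design"] is not None:
        block = kwargs["design"]
        valid = set(CohortDesign.__dataclass_fields__)
        unknown = set(block) - valid
        if unknown:
            raise ConfigError(f"unknown design key(s): {sorted(unknown)}")
        for key in ("age_range", "tbw_range", "duration_range", "delay_range",
                    "crcl_range"):
            if key in block:
                block[key] = tuple(block[key])
        kwargs["design"] = CohortDesign(**block)
    if "saem" in kwargs and kwargs["saem"] is not None:
        block = kwargs["saem"]
        valid = set(SAEMSettings.__dataclass_fields__)
        unknown = set(block) - valid
        if unknown:
            raise ConfigError(f"unknown saem key(s): {sorted(unknown)}")
        kwargs["saem"] = SAEMSettings(**block)
    for key in ("candidate_parameters", "candidate_covariates", "scenario_crcl",
                "stages"):
        if key in kwargs:
            kwargs[key] = tuple(kwargs[key])
    return RunConfig(**kwargs)
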