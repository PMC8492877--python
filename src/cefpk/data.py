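"""NONMEM-convention longitudinal event dataset.

Records follow the classic columns ID / TIME / AMT / DV / EVID / MDV with
covariates as additional, time-constant-per-subject columns.  Dose records
have EVID=1 and a positive AMT; observation records have EVID=0 and a DV in
mg/L.  Observations below the assay's lower limit of quantification carry
BLQ=1 and are excluded from estimation (with a logged count).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core_model import CovariateSet, DoseEvent

logger = logging.getLogger("cefpk")

REQUIRED_COLUMNS = ("ID", "TIME", "AMT", "DV", "EVID", "MDV")
COVARIATE_COLUMNS = {
    "AGE": "age",
    "SEX": "sex",
    "TBW": "tbw",
    "HEIGHT": "height",
    "BMI": "bmi",
    "SCR": "scr",
    "CRCL_CG": "crcl_cg",
    "CRCL_CKDEPI": "crcl_ckdepi",
    "LBW": "lbw",
}


class DatasetError(ValueError):
    """Raised when an event dataset violates the schema."""


@dataclass
class Packed:
    """Padded per-subject arrays for the vectorized likelihood engine."""

    ids: np.ndarray          # (N,) subject ids
    y: np.ndarray            # (N, J) observed concentrations, NaN-padded
    t_obs: np.ndarray        # (N, J) observation times
    obs_mask: np.ndarray     # (N, J) True where a usable (non-BLQ) observation sits
    blq_mask: np.ndarray     # (N, J) True where an observation is below the LLOQ
    dose_amt: np.ndarray     # (N, D) dose amounts, 0-padded
    dose_t: np.ndarray       # (N, D) dose times

    @property
    def n_subjects(self) -> int:
        return len(self.ids)

    @property
    def n_obs(self) -> int:
        return int(self.obs_mask.sum())


@dataclass
class EventDataset:
    """Dosing and observation records plus per-subject covariates."""

    df: pd.DataFrame
    covariates: dict = field(default_factory=dict)   # id -> CovariateSet

    def __post_init__(self):
        self.df = self.df.reset_index(drop=True)
        if not self.covariates:
            self.covariates = _covariates_from_frame(self.df)
        self.validate()

    # -- schema ------------------------------------------------------------
    def validate(self):
        df = self.df
        missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
        if missing:
            raise DatasetError(f"missing required columns: {missing}")
        if (df["TIME"] < 0).any():
            row = int(df.index[df["TIME"] < 0][0])
            raise DatasetError(f"negative TIME at row {row}")
        dose_rows = df["EVID"] == 1
        obs_rows = df["EVID"] == 0
        bad = dose_rows & df["DV"].notna()
        if bad.any():
            raise DatasetError(f"DV present on dose (EVID=1) row {int(df.index[bad][0])}")
        bad = obs_rows & (df["AMT"].fillna(0) > 0)
        if bad.any():
            raise DatasetError(f"AMT present on observation (EVID=0) row {int(df.index[bad][0])}")
        bad = dose_rows & ~(df["AMT"] > 0)
        if bad.any():
            raise DatasetError(f"non-positive AMT on dose row {int(df.index[bad][0])}")
        for sid, sub in df.groupby("ID", sort=False):
            if not (sub["EVID"] == 1).any():
                raise DatasetError(f"subject {sid} has no dose record")
            if not (sub["EVID"] == 0).any():
                raise DatasetError(f"subject {sid} has no observation record")
            t = sub["TIME"].to_numpy()
            if np.any(np.diff(t) < 0):
                row = int(sub.index[1:][np.diff(t) < 0][0])
                raise DatasetError(f"non-monotone TIME within subject {sid} at row {row}")

    # -- convenience accessors ----------------------------------------------
    @property
    def subject_ids(self) -> list:
        return list(dict.fromkeys(self.df["ID"].tolist()))

    @property
    def n_subjects(self) -> int:
        return len(self.subject_ids)

    @property
    def n_observations(self) -> int:
        return int((self.df["EVID"] == 0).sum())

    @property
    def n_blq(self) -> int:
        if "BLQ" not in self.df.columns:
            return 0
        return int(((self.df["EVID"] == 0) & (self.df["BLQ"] == 1)).sum())

    def doses_for(self, subject_id) -> list:
        sub = self.df[(self.df["ID"] == subject_id) & (self.df["EVID"] == 1)]
        return [DoseEvent(time=r.TIME, amount=r.AMT) for r in sub.itertuples()]

    def pack(self) -> Packed:
        """Pad per-subject records into rectangular arrays."""
        ids = self.subject_ids
        obs = self.df[self.df["EVID"] == 0]
        dos = self.df[self.df["EVID"] == 1]
        has_blq = "BLQ" in self.df.columns
        J = int(obs.groupby("ID").size().max())
        D = int(dos.groupby("ID").size().max())
        N = len(ids)
        y = np.full((N, J), np.nan)
        t_obs = np.zeros((N, J))
        omask = np.zeros((N, J), dtype=bool)
        bmask = np.zeros((N, J), dtype=bool)
        damt = np.zeros((N, D))
        dt = np.zeros((N, D))
        for i, sid in enumerate(ids):
            o = obs[obs["ID"] == sid]
            k = len(o)
            y[i, :k] = o["DV"].to_numpy()
            t_obs[i, :k] = o["TIME"].to_numpy()
            blq = o["BLQ"].to_numpy().astype(bool) if has_blq else np.zeros(k, dtype=bool)
            bmask[i, :k] = blq
            omask[i, :k] = ~blq
            d = dos[dos["ID"] == sid]
            damt[i, : len(d)] = d["AMT"].to_numpy()
            dt[i, : len(d)] = d["TIME"].to_numpy()
        return Packed(np.asarray(ids), y, t_obs, omask, bmask, damt, dt)

    # -- round-trip helpers --------------------------------------------------
    def equals(self, other: "EventDataset") -> bool:
        a = self.df.fillna(-1).reset_index(drop=True)
        b = other.df.fillna(-1).reset_index(drop=True)
        if list(a.columns) != list(b.columns) or len(a) != len(b):
            return False
        for c in a.columns:
            col_a, col_b = a[c], b[c]
            if np.issubdtype(col_a.dtype, np.number) and np.issubdtype(col_b.dtype, np.number):
                if not np.allclose(col_a.to_numpy(dtype=float), col_b.to_numpy(dtype=float),
                                   rtol=1e-12, atol=1e-12):
                    return False
            elif not col_a.astype(str).equals(col_b.astype(str)):
                return False
        return True


def _covariates_from_frame(df: pd.DataFrame) -> dict:
    out = {}
    present = [c for c in COVARIATE_COLUMNS if c in df.columns]
    for sid, sub in df.groupby("ID", sort=False):
        first = sub.iloc[0]
        kwargs = {}
        for col in present:
            value = first[col]
            if pd.isna(value):
                continue
            kwargs[COVARIATE_COLUMNS[col]] = value if col == "SEX" else float(value)
        out[sid] = CovariateSet(**kwargs) if kwargs else CovariateSet()
    return out


def build_records(subject_id, doses, times, values, blq_flags, cov: CovariateSet) -> pd.DataFrame:
    """Assemble one subject's dose + observation rows in NONMEM convention."""
    rows = []
    cov_cols = {
        "AGE": cov.age, "SEX": cov.sex, "TBW": cov.tbw, "HEIGHT": cov.height,
        "BMI": cov.bmi, "SCR": cov.scr_umol_l() if cov.scr is not None else np.nan,
        "CRCL_CG": cov.crcl_cg, "CRCL_CKDEPI": cov.crcl_ckdepi, "LBW": cov.lbw,
    }
    for d in doses:
        rows.append({"ID": subject_id, "TIME": d.time, "AMT": d.amount, "DV": np.nan,
                     "EVID": 1, "MDV": 1, "BLQ": 0, **cov_cols})
    for t, v, blq in zip(times, values, blq_flags):
        rows.append({"ID": subject_id, "TIME": t, "AMT": np.nan, "DV": v,
                     "EVID": 0, "MDV": 0, "BLQ": int(blq), **cov_cols})
    df = pd.DataFrame(rows).sort_values(["TIME", "EVID"], ascending=[True, False], kind="stable")
    return df.reset_index(drop=True)
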