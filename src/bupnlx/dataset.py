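"""Event-oriented longitudinal PK dataset (NONMEM-style CSV layout).

Columns
-------
ID        subject identifier (int)
TIME      hours since first dose (>= 0, sorted within subject)
AMT       dose amount in ng (dose rows only)
EVID      1 for dose rows, 0 for observation rows
CMT       analyte of an observation: BUP, NORBUP or NLX (dose rows: DOSE)
DV        observed concentration, ng/L (empty for dose rows and BQL rows)
BQL       1 if the observation is below the quantification limit
LLOQ      lower limit of quantification for the analyte, ng/L
NOS       number of swallows attached to the subject's dose events
DOSEGRP   labelled dose tier, mg
ARM       study-arm name
STATE     healthy / OUD
AGE, WT, HT  demographics (years, kg, m)

An in-memory dataset may additionally carry a ``DV_TRUE`` column holding the
uncensored simulated value; it is internal and never written to disk.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

ANALYTES = ("BUP", "NORBUP", "NLX")
LLOQ_DEFAULT = {"BUP": 50.0, "NORBUP": 50.0, "NLX": 20.0}

COLUMNS = ["ID", "TIME", "AMT", "EVID", "CMT", "DV", "BQL", "LLOQ",
           "NOS", "DOSEGRP", "ARM", "STATE", "AGE", "WT", "HT"]


class DatasetError(ValueError):
    """Aggregated schema violations, with row numbers."""


class PKDataset:
    """Validated longitudinal PK dataset wrapping a pandas DataFrame."""

    def __init__(self, df: pd.DataFrame, meta: dict | None = None, validate: bool = True):
        self.df = df.reset_index(drop=True)
        self.meta = dict(meta or {})
        if validate:
            self.validate()

    # -- construction / IO --------------------------------------------------
    @classmethod
    def read_csv(cls, path) -> "PKDataset":
        df = pd.read_csv(path)
        missing = [c for c in COLUMNS if c not in df.columns]
        if missing:
            raise DatasetError(f"missing columns: {missing}")
        return cls(df)

    def write_csv(self, path) -> None:
        out = self.df[COLUMNS].copy()
        out.to_csv(path, index=False, float_format="%.10g")

    # -- validation ----------------------------------------------------------
    def validate(self) -> None:
        df = self.df
        errors: list[str] = []
        missing = [c for c in COLUMNS if c not in df.columns]
        if missing:
            raise DatasetError(f"missing columns: {missing}")
        if df.empty:
            raise DatasetError("dataset is empty")
        for i, row in df.iterrows():
            if row.TIME < 0:
                errors.append(f"row {i}: negative TIME")
            if row.EVID == 1:
                if not row.AMT > 0:
                    errors.append(f"row {i}: dose row requires AMT > 0")
                if pd.notna(row.DV):
                    errors.append(f"row {i}: dose row must not carry DV")
            elif row.EVID == 0:
                if pd.notna(row.AMT) and row.AMT > 0:
                    errors.append(f"row {i}: observation row must not carry AMT")
                if row.CMT not in ANALYTES:
                    errors.append(f"row {i}: unknown analyte {row.CMT!r}")
                if row.BQL == 1 and pd.notna(row.DV):
                    logger.warning("row %d: BQL record carries a DV; DV ignored, "
                                   "treated as censored", i)
                    self.df.loc[i, "DV"] = np.nan
                if row.BQL == 0 and pd.isna(row.DV):
                    errors.append(f"row {i}: quantifiable observation lacks DV")
            else:
                errors.append(f"row {i}: EVID must be 0 or 1")
        for sid, g in df.groupby("ID"):
            if not g.TIME.is_monotonic_increasing:
                errors.append(f"subject {sid}: TIME not sorted")
        if errors:
            raise DatasetError("; ".join(errors[:20]) +
                               (f" (+{len(errors)-20} more)" if len(errors) > 20 else ""))

    # -- accessors -----------------------------------------------------------
    @property
    def subjects(self) -> np.ndarray:
        return self.df.ID.unique()

    def observations(self, analyte: str | None = None, arm: str | None = None,
                     include_bql: bool = True) -> pd.DataFrame:
        obs = self.df[self.df.EVID == 0]
        if analyte is not None:
            obs = obs[obs.CMT == analyte]
        if arm is not None:
            obs = obs[obs.ARM == arm]
        if not include_bql:
            obs = obs[obs.BQL == 0]
        return obs

    def doses(self, subject=None) -> pd.DataFrame:
        d = self.df[self.df.EVID == 1]
        return d if subject is None else d[d.ID == subject]

    def bql_fraction(self, analyte: str, arm: str | None = None) -> float:
        obs = self.observations(analyte, arm)
        if obs.empty:
            raise DatasetError(f"no observations for analyte {analyte!r}")
        return float((obs.BQL == 1).mean())

    def subject_data(self, subject) -> pd.DataFrame:
        return self.df[self.df.ID == subject]


def read_dataset(path) -> PKDataset:
    """Read and validate a PK dataset CSV."""
    return PKDataset.read_csv(path)


def write_dataset(dataset: PKDataset, path) -> None:
    """Write a PK dataset to CSV (internal-only columns dropped)."""
    dataset.write_csv(path)
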