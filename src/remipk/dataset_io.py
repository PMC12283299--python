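"""Read/write/validate the rectangular dosing-observation dataset.

The on-disk format is a plain comma-separated file following the NONMEM
column convention: one row per dose segment (EVID=1, MDV=1, AMT mg, RATE
mg/h) or observation (EVID=0, MDV=0, DV ng/mL), times in hours relative to
each subject's first dose, plus per-subject covariate columns repeated on
every row.  Infusion duration is implied by AMT/RATE; no zero-rate "off"
rows are used (superposition handles switch-off exactly).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator

import numpy as np
import pandas as pd
import yaml

from .pkcore import DoseEvent, Regimen

__all__ = [
    "REQUIRED_COLUMNS",
    "COVARIATE_COLUMNS",
    "Dataset",
    "SubjectData",
    "DatasetError",
    "read_dataset",
    "write_dataset",
    "validate_dataset",
    "load_config",
]

REQUIRED_COLUMNS = ["ID", "TIME", "AMT", "RATE", "EVID", "DV", "MDV", "BLQ"]
COVARIATE_COLUMNS = [
    "AGE", "WT", "SEX", "ALT", "SCR", "TP", "ALB", "ECMO", "CRRT", "CRCL", "EGFR",
]

#: Upper end of the assay's validated linear range, ng/mL.
ASSAY_UPPER = 1000.0


class DatasetError(ValueError):
    """Raised for structurally invalid datasets (hard errors, not findings)."""


@dataclass(frozen=True)
class SubjectData:
    """One subject's regimen, observations, and covariates, engine-ready."""

    subject_id: int
    regimen: Regimen
    times: np.ndarray          # observation times, h
    dv: np.ndarray             # observed concentrations, ng/mL
    blq: np.ndarray            # below-LLOQ flags (bool)
    covariates: dict = field(default_factory=dict)


@dataclass
class Dataset:
    """Typed wrapper around the rectangular dosing/observation table."""

    frame: pd.DataFrame

    def __post_init__(self) -> None:
        self.frame = _coerce_and_check(self.frame)

    # -- basic accessors ---------------------------------------------------

    @property
    def subject_ids(self) -> np.ndarray:
        return self.frame["ID"].unique()

    @property
    def n_subjects(self) -> int:
        return len(self.subject_ids)

    @property
    def n_observations(self) -> int:
        return int((self.frame["EVID"] == 0).sum())

    def observations(self, drop_blq: bool = True) -> pd.DataFrame:
        """Observation rows; BLQ-flagged rows are excluded from fitting by default."""
        obs = self.frame[self.frame["EVID"] == 0]
        if drop_blq:
            obs = obs[obs["BLQ"] == 0]
        return obs

    def subjects(self, drop_blq: bool = True) -> Iterator[SubjectData]:
        for sid, grp in self.frame.groupby("ID", sort=True):
            doses = grp[grp["EVID"] == 1]
            events = tuple(
                DoseEvent(start=row.TIME, rate=row.RATE, duration=row.AMT / row.RATE)
                for row in doses.itertuples()
            )
            obs = grp[grp["EVID"] == 0]
            if drop_blq:
                obs = obs[obs["BLQ"] == 0]
            cov_row = grp.iloc[0]
            covs = {c: cov_row[c] for c in COVARIATE_COLUMNS if c in grp.columns}
            yield SubjectData(
                subject_id=int(sid),
                regimen=Regimen(events),
                times=obs["TIME"].to_numpy(float),
                dv=obs["DV"].to_numpy(float),
                blq=obs["BLQ"].to_numpy(int).astype(bool),
                covariates=covs,
            )

    def subset(self, subject_ids, renumber: bool = False) -> "Dataset":
        """Dataset restricted to the given ids; ids may repeat (bootstrap).

        With ``renumber=True`` each occurrence becomes a fresh consecutive ID,
        so a subject drawn twice contributes two independent records.
        """
        parts = []
        for new_id, sid in enumerate(subject_ids, start=1):
            block = self.frame[self.frame["ID"] == sid].copy()
            if block.empty:
                raise DatasetError(f"unknown subject id {sid!r}")
            if renumber:
                block["ID"] = new_id
            parts.append(block)
        return Dataset(pd.concat(parts, ignore_index=True))

    def covariate_median(self, column: str) -> float:
        """Median of a covariate across subjects (one value per subject)."""
        per_subject = self.frame.groupby("ID")[column].first()
        return float(per_subject.median())


def _coerce_and_check(frame: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in REQUIRED_COLUMNS if c not in frame.columns]
    if missing:
        raise DatasetError(f"missing required column(s): {', '.join(missing)}")
    frame = frame.copy()
    for col in ("ID", "EVID", "MDV", "BLQ"):
        frame[col] = frame[col].astype(int)
    for col in ("TIME", "AMT", "RATE"):
        frame[col] = frame[col].astype(float)
    frame["DV"] = pd.to_numeric(frame["DV"], errors="coerce")

    # canonical order: by subject, time, doses before observations at a tie
    frame = frame.sort_values(
        ["ID", "TIME", "EVID"], ascending=[True, True, False], kind="mergesort"
    ).reset_index(drop=True)

    obs = frame["EVID"] == 0
    dose = frame["EVID"] == 1
    blank_dv = frame["DV"].isna()
    bad = frame[obs & blank_dv]
    if not bad.empty:
        row = bad.iloc[0]
        raise DatasetError(
            f"observation row with blank DV: ID={int(row.ID)} TIME={row.TIME:g}"
        )
    bad = frame[obs & (frame["DV"] < 0)]
    if not bad.empty:
        row = bad.iloc[0]
        raise DatasetError(
            f"negative DV: ID={int(row.ID)} TIME={row.TIME:g} DV={row.DV:g}"
        )
    bad = frame[dose & (frame["RATE"] <= 0) & (frame["AMT"] > 0)]
    if not bad.empty:
        row = bad.iloc[0]
        raise DatasetError(
            "dose row with RATE=0 and AMT>0 (ambiguous bolus): "
            f"ID={int(row.ID)} TIME={row.TIME:g}"
        )
    if (frame.loc[dose, "MDV"] != 1).any():
        raise DatasetError("dose rows must carry MDV=1")

    for sid, grp in frame.groupby("ID"):
        if not (grp["EVID"] == 1).any():
            raise DatasetError(f"subject {sid} has no dose row")
        if not (grp["EVID"] == 0).any():
            raise DatasetError(f"subject {sid} has no observation row")
    return frame


def read_dataset(path) -> Dataset:
    """Read and validate a dataset CSV (decimal point, comma separator)."""
    frame = pd.read_csv(path, sep=",")
    return Dataset(frame)


def write_dataset(ds: Dataset, path) -> None:
    """Write the canonical CSV; ``read_dataset(write_dataset(ds))`` round-trips."""
    out = ds.frame.copy()
    out.to_csv(path, sep=",", index=False, float_format="%.10g")


@dataclass(frozen=True)
class Finding:
    level: str      # "error" | "warning"
    message: str

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return f"[{self.level}] {self.message}"


def validate_dataset(ds: Dataset) -> list:
    """Report (never raise) data-quality findings on a parsed dataset.

    Errors: negative DV (unreachable through the constructor, but reported for
    frames assembled by hand).  Warnings: observations before the first dose;
    concentrations above the assay's validated range (kept, not dropped).
    """
    findings: list[Finding] = []
    frame = ds.frame
    obs = frame[frame["EVID"] == 0]
    neg = obs[obs["DV"] < 0]
    for row in neg.itertuples():
        findings.append(Finding("error", f"negative DV at ID={row.ID} TIME={row.TIME:g}"))
    high = obs[obs["DV"] > ASSAY_UPPER]
    for row in high.itertuples():
        findings.append(
            Finding(
                "warning",
                f"DV={row.DV:g} ng/mL above assay linear range ({ASSAY_UPPER:g}) "
                f"at ID={row.ID} TIME={row.TIME:g}",
            )
        )
    for sid, grp in frame.groupby("ID"):
        first_dose = grp.loc[grp["EVID"] == 1, "TIME"].min()
        early = grp[(grp["EVID"] == 0) & (grp["TIME"] < first_dose)]
        if not early.empty:
            findings.append(
                Finding("warning", f"observation before first dose for ID={sid}")
            )
    return findings


def load_config(path) -> dict:
    """Load a YAML run configuration with [data]/[model]/[estimation]/[simulation] sections."""
    with open(path) as fh:
        cfg = yaml.safe_load(fh) or {}
    if not isinstance(cfg, dict):
        raise DatasetError(f"config {path} must be a mapping")
    return cfg
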