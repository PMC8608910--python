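"""Subject records and NONMEM-style rectangular dataset I/O.

The on-disk format is a plain CSV with the conventional pharmacometric
columns ``ID, TIME, DV, AMT, EVID`` plus covariate columns
``AGE, SEXF, WT, HT, CR, CC`` (SEXF: 1 = female).  Each subject has exactly
one dose record (EVID = 1, AMT = dose in mg at TIME = 0) and any number of
observation records (EVID = 0, DV in µg/mL).  Reading is header-driven, so
column order is irrelevant.  Simulation truth (true η, true clearance,
noiseless concentrations) is written to a sidecar file, never into the
analysis dataset.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .pk_models import Covariates

__all__ = ["SubjectRecord", "DatasetParseError", "read_dataset", "write_dataset"]


class DatasetParseError(ValueError):
    """The dataset file violates the expected rectangular layout."""


@dataclass(frozen=True)
class SubjectRecord:
    """One subject's dose, observations and covariates."""

    subject_id: int
    dose_mg: float
    times: np.ndarray
    concentrations: np.ndarray
    covariates: Covariates | None = None

    def __post_init__(self) -> None:
        times = np.asarray(self.times, dtype=float)
        conc = np.asarray(self.concentrations, dtype=float)
        if times.shape != conc.shape:
            raise DatasetParseError(
                f"subject {self.subject_id}: times and concentrations differ in length"
            )
        order = np.argsort(times, kind="stable")
        object.__setattr__(self, "times", times[order])
        object.__setattr__(self, "concentrations", conc[order])
        if not self.dose_mg > 0:
            raise DatasetParseError(f"subject {self.subject_id}: dose must be positive")

    @property
    def n_obs(self) -> int:
        return self.times.size

    def restricted(self, times: np.ndarray, atol: float = 1e-9) -> "SubjectRecord":
        """Copy keeping only observations at the given times (all must exist)."""
        wanted = np.asarray(times, dtype=float)
        idx = []
        for t in wanted:
            hits = np.flatnonzero(np.isclose(self.times, t, rtol=0.0, atol=atol))
            if hits.size == 0:
                raise DatasetParseError(
                    f"subject {self.subject_id} has no observation at t={t} min"
                )
            idx.append(hits[0])
        sel = np.asarray(idx, dtype=int)
        return SubjectRecord(
            subject_id=self.subject_id,
            dose_mg=self.dose_mg,
            times=self.times[sel],
            concentrations=self.concentrations[sel],
            covariates=self.covariates,
        )

    def excluding_time(self, t: float, atol: float = 1e-9) -> "SubjectRecord":
        keep = ~np.isclose(self.times, t, rtol=0.0, atol=atol)
        return SubjectRecord(
            subject_id=self.subject_id,
            dose_mg=self.dose_mg,
            times=self.times[keep],
            concentrations=self.concentrations[keep],
            covariates=self.covariates,
        )

    def observation_at(self, t: float, atol: float = 1e-9) -> float:
        hits = np.flatnonzero(np.isclose(self.times, t, rtol=0.0, atol=atol))
        if hits.size == 0:
            raise DatasetParseError(
                f"subject {self.subject_id} has no observation at t={t} min"
            )
        return float(self.concentrations[hits[0]])


_COVARIATE_COLS = ("AGE", "SEXF", "WT", "CR", "CC")


def _covariates_from_row(row: pd.Series) -> Covariates | None:
    if not all(c in row.index and not pd.isna(row[c]) for c in _COVARIATE_COLS):
        return None
    height = None
    if "HT" in row.index and not pd.isna(row["HT"]):
        height = float(row["HT"])
    return Covariates(
        age=float(row["AGE"]),
        sex="female" if int(row["SEXF"]) == 1 else "male",
        weight=float(row["WT"]),
        creatinine=float(row["CR"]),
        cystatin_c=float(row["CC"]),
        height=height,
    )


def read_dataset(path: str | Path) -> list[SubjectRecord]:
    """Parse a NONMEM-style CSV into subject records (header-driven)."""
    path = Path(path)
    df = pd.read_csv(path, na_values=["."])
    required = {"ID", "TIME", "DV", "AMT", "EVID"}
    missing = required - set(df.columns)
    if missing:
        raise DatasetParseError(f"{path}: missing required columns {sorted(missing)}")
    subjects: list[SubjectRecord] = []
    for sid, group in df.groupby("ID", sort=True):
        doses = group[group["EVID"] == 1]
        if len(doses) != 1:
            raise DatasetParseError(
                f"{path}: subject {sid} has {len(doses)} dose records, expected 1"
            )
        obs = group[group["EVID"] == 0]
        bad = obs[obs["DV"].isna()]
        if len(bad):
            row_no = int(bad.index[0]) + 2  # 1-based, plus header line
            raise DatasetParseError(
                f"{path}: missing DV in observation record at line {row_no}"
            )
        subjects.append(
            SubjectRecord(
                subject_id=int(sid),
                dose_mg=float(doses["AMT"].iloc[0]),
                times=obs["TIME"].to_numpy(dtype=float),
                concentrations=obs["DV"].to_numpy(dtype=float),
                covariates=_covariates_from_row(group.iloc[0]),
            )
        )
    if not subjects:
        raise DatasetParseError(f"{path}: no subjects found")
    return subjects


def _fmt(x: float) -> str:
    return f"{x:.12g}"


def write_dataset(subjects, path: str | Path) -> Path:
    """Write subject records (or simulated subjects) as NONMEM-style CSV.

    Accepts :class:`SubjectRecord` or any object with a ``.record`` attribute
    (e.g. :class:`iohexolpk.simulate.SimulatedSubject`); for simulated
    subjects a truth sidecar ``<stem>_truth.csv`` is written next to the
    dataset.  Numbers are written to 12 significant digits, so a write/read
    round trip is lossless at that precision.
    """
    path = Path(path)
    rows = []
    truth_rows = []
    for item in subjects:
        rec: SubjectRecord = getattr(item, "record", item)
        cov = rec.covariates
        covvals = {
            "AGE": _fmt(cov.age) if cov else ".",
            "SEXF": str(int(cov.is_female)) if cov else ".",
            "WT": _fmt(cov.weight) if cov else ".",
            "HT": _fmt(cov.height) if cov and cov.height is not None else ".",
            "CR": _fmt(cov.creatinine) if cov else ".",
            "CC": _fmt(cov.cystatin_c) if cov else ".",
        }
        rows.append(
            {"ID": rec.subject_id, "TIME": "0", "DV": ".", "AMT": _fmt(rec.dose_mg),
             "EVID": 1, **covvals}
        )
        for t, c in zip(rec.times, rec.concentrations):
            rows.append(
                {"ID": rec.subject_id, "TIME": _fmt(t), "DV": _fmt(c), "AMT": ".",
                 "EVID": 0, **covvals}
            )
        if hasattr(item, "true_eta"):
            base = {"ID": rec.subject_id, "TRUE_CL_ML_MIN": _fmt(item.true_cl_ml_min)}
            for name, e in zip(item.re_mask, item.true_eta):
                base[f"TRUE_ETA_{name}"] = _fmt(e)
            for t, c in zip(rec.times, item.noiseless):
                truth_rows.append({**base, "TIME": _fmt(t), "CONC_NOISELESS": _fmt(c)})
    pd.DataFrame(rows).to_csv(path, index=False)
    if truth_rows:
        sidecar = path.with_name(path.stem + "_truth.csv")
        pd.DataFrame(truth_rows).to_csv(sidecar, index=False)
    return path
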