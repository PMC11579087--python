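"""Subject-level data containers and the NONMEM-flavoured CSV layout.

A dataset is a rectangular table with columns ``id, time, amount, duration,
dv`` plus one column per covariate.  Dose rows leave ``dv`` empty;
observation rows leave ``amount`` empty (or zero).  Covariates are constant
within a subject.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .pk import DoseEvent

#: Covariates carried on every subject. Only weight and VWF:Ag enter the
#: simulation truth model; the rest are available to covariate models.
COVARIATE_NAMES = ("weight", "vwf", "age", "height", "blood_group")


@dataclass(frozen=True)
class CovariateVector:
    """Patient covariates: body weight (kg), VWF:Ag (% of normal), and
    optionally age (years), height (cm) and ABO blood group."""

    weight: float
    vwf: float
    age: float = np.nan
    height: float = np.nan
    blood_group: str = ""

    def __post_init__(self):
        if self.weight <= 0:
            raise ValueError(f"weight must be > 0, got {self.weight}")
        if self.vwf < 0:
            raise ValueError(f"VWF:Ag must be >= 0, got {self.vwf}")


@dataclass
class SubjectRecord:
    """One individual: covariates, dosing history and observed levels."""

    id: int | str
    covariates: CovariateVector
    doses: list[DoseEvent]
    obs_times: np.ndarray
    obs_values: np.ndarray
    true_eta: np.ndarray | None = None  # simulation only

    def __post_init__(self):
        self.obs_times = np.asarray(self.obs_times, dtype=float)
        self.obs_values = np.asarray(self.obs_values, dtype=float)
        if self.obs_times.shape != self.obs_values.shape:
            raise ValueError("obs_times and obs_values must have equal length")

    @property
    def n_obs(self) -> int:
        return int(self.obs_times.size)


def subjects_to_frame(subjects: list[SubjectRecord]) -> pd.DataFrame:
    rows = []
    for s in subjects:
        cov = s.covariates
        base = {
            "id": s.id,
            "weight": cov.weight,
            "vwf": cov.vwf,
            "age": cov.age,
            "height": cov.height,
            "blood_group": cov.blood_group,
        }
        for d in s.doses:
            rows.append(
                base | {"time": d.time, "amount": d.amount, "duration": d.duration, "dv": np.nan}
            )
        for t, y in zip(s.obs_times, s.obs_values):
            rows.append(base | {"time": t, "amount": np.nan, "duration": np.nan, "dv": y})
    cols = ["id", "time", "amount", "duration", "dv", *COVARIATE_NAMES]
    return pd.DataFrame(rows, columns=cols)


def frame_to_subjects(df: pd.DataFrame) -> list[SubjectRecord]:
    subjects = []
    for sid, grp in df.groupby("id", sort=False):
        first = grp.iloc[0]
        cov = CovariateVector(
            weight=float(first["weight"]),
            vwf=float(first["vwf"]),
            age=float(first.get("age", np.nan)),
            height=float(first.get("height", np.nan)),
            blood_group=str(first.get("blood_group", "") or ""),
        )
        dose_rows = grp[grp["dv"].isna()]
        obs_rows = grp[grp["dv"].notna()].sort_values("time")
        doses = [
            DoseEvent(float(r["time"]), float(r["amount"]), float(r["duration"] or 0.0))
            for _, r in dose_rows.iterrows()
        ]
        subjects.append(
            SubjectRecord(
                id=sid,
                covariates=cov,
                doses=doses,
                obs_times=obs_rows["time"].to_numpy(float),
                obs_values=obs_rows["dv"].to_numpy(float),
            )
        )
    return subjects


def write_dataset(subjects: list[SubjectRecord], path, sidecar: dict | None = None) -> None:
    """Write the rectangular CSV; optional JSON sidecar with simulation truth."""
    subjects_to_frame(subjects).to_csv(path, index=False)
    if sidecar is not None:
        with open(str(path) + ".json", "w") as fh:
            json.dump(sidecar, fh, indent=2, default=_json_default)


def read_dataset(path) -> list[SubjectRecord]:
    return frame_to_subjects(pd.read_csv(path))


def _json_default(obj):
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    raise TypeError(f"not JSON serializable: {type(obj)}")


@dataclass
class SubjectBatch:
    """Padded rectangular view of a subject list, for vectorized objectives.

    Observation/dose arrays are constants; ``mask`` marks real observations.
    """

    y: np.ndarray  # (n, T) observed levels, 0 where padded
    times: np.ndarray  # (n, T) observation times
    mask: np.ndarray  # (n, T) 1.0 for real observations
    dose_times: np.ndarray  # (n, K)
    dose_amounts: np.ndarray  # (n, K), 0 where padded
    dose_durations: np.ndarray  # (n, K)
    covariates: dict[str, np.ndarray] = field(default_factory=dict)
    ids: list = field(default_factory=list)

    @property
    def n_subjects(self) -> int:
        return self.y.shape[0]

    @property
    def n_obs(self) -> float:
        return float(self.mask.sum())

    @classmethod
    def from_subjects(cls, subjects: list[SubjectRecord]) -> "SubjectBatch":
        n = len(subjects)
        if n == 0:
            raise ValueError("empty subject list")
        T = max(s.n_obs for s in subjects)
        K = max(max(len(s.doses), 1) for s in subjects)
        y = np.zeros((n, T))
        times = np.zeros((n, T))
        mask = np.zeros((n, T))
        d_t = np.zeros((n, K))
        d_a = np.zeros((n, K))
        d_d = np.zeros((n, K))
        for i, s in enumerate(subjects):
            m = s.n_obs
            y[i, :m] = s.obs_values
            times[i, :m] = s.obs_times
            mask[i, :m] = 1.0
            for k, d in enumerate(s.doses):
                d_t[i, k], d_a[i, k], d_d[i, k] = d.time, d.amount, d.duration
        cov = {
            name: np.array(
                [getattr(s.covariates, name) for s in subjects],
                dtype=object if name == "blood_group" else float,
            )
            for name in COVARIATE_NAMES
        }
        return cls(y, times, mask, d_t, d_a, d_d, cov, [s.id for s in subjects])
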