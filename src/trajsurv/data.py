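"""Core data containers, readers/writers, eligibility filtering and cohort summaries.

The universal input is a :class:`JointDataset`: a subject-level table
(survival outcome plus baseline covariates) paired with a long-format table
of repeated biomarker measurements.  The biomarker (CD4 lymphocyte count,
cells/mm^3) is modeled on a root-transformed scale to tame its right skew;
the fourth root is the default, the square root is available by
configuration.  Covariate coding is fixed throughout the package: ``sex``
1=female, ``addiction`` 1=no history of addiction, ``age`` in years at
diagnosis (the time origin for both processes).
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from typing import Iterable, NamedTuple

import numpy as np
import pandas as pd

SUBJECT_COLUMNS = ["subject_id", "event_time", "event", "sex", "addiction", "age"]
MEASUREMENT_COLUMNS = ["subject_id", "time", "cd4"]

TRANSFORMS = {"fourth_root": 0.25, "square_root": 0.5}


class DataError(ValueError):
    """Raised when an input table violates the dataset contract."""


@dataclass(frozen=True)
class CovariateVector:
    """Baseline covariates: sex (1=female), addiction (1=no history), age in years."""

    sex: int
    addiction: int
    age: float

    def __post_init__(self) -> None:
        if self.sex not in (0, 1) or self.addiction not in (0, 1):
            raise DataError("sex and addiction must be 0/1 indicators")
        if not self.age > 0:
            raise DataError("age must be positive")

    def as_array(self) -> np.ndarray:
        return np.array([self.sex, self.addiction, self.age], dtype=float)


@dataclass(frozen=True)
class SurvivalRecord:
    """Time to event (years since diagnosis) and event indicator (1=death)."""

    subject_id: str
    event_time: float
    event: int

    def __post_init__(self) -> None:
        if not self.event_time > 0:
            raise DataError(f"event_time must be > 0 (subject {self.subject_id})")
        if self.event not in (0, 1):
            raise DataError(f"event must be 0/1 (subject {self.subject_id})")


@dataclass(frozen=True)
class LongitudinalRecord:
    """One biomarker measurement: raw count and its transformed value."""

    subject_id: str
    time: float
    marker_raw: float
    marker: float

    def __post_init__(self) -> None:
        if self.time < 0:
            raise DataError(f"measurement time must be >= 0 (subject {self.subject_id})")
        if self.marker_raw < 0:
            raise DataError(f"marker_raw must be >= 0 (subject {self.subject_id})")


def transform_marker(cd4, mode: str = "fourth_root"):
    """Root-transform a raw biomarker count.

    Parameters
    ----------
    cd4 : scalar or array-like, >= 0
    mode : {"fourth_root", "square_root"}

    Returns the transformed value(s); strictly increasing in ``cd4``.
    """
    if mode not in TRANSFORMS:
        raise ValueError(f"unknown transform mode {mode!r}")
    arr = np.asarray(cd4, dtype=float)
    if np.any(arr < 0):
        raise DataError("cd4 counts must be non-negative")
    out = np.power(arr, TRANSFORMS[mode])
    return float(out) if np.isscalar(cd4) else out


def inverse_transform_marker(y, mode: str = "fourth_root"):
    """Inverse of :func:`transform_marker` for y >= 0."""
    if mode not in TRANSFORMS:
        raise ValueError(f"unknown transform mode {mode!r}")
    arr = np.asarray(y, dtype=float)
    if np.any(arr < 0):
        raise DataError("transformed values must be non-negative")
    out = np.power(arr, 1.0 / TRANSFORMS[mode])
    return float(out) if np.isscalar(y) else out


@dataclass
class JointDataset:
    """Paired longitudinal and subject-level tables.

    ``subjects`` columns: subject_id, event_time, event, sex, addiction, age.
    ``measurements`` columns: subject_id, time, marker_raw, marker.
    """

    subjects: pd.DataFrame
    measurements: pd.DataFrame
    transform: str = "fourth_root"
    report: list = field(default_factory=list)

    def __post_init__(self) -> None:
        self.subjects = self.subjects.reset_index(drop=True)
        self.measurements = self.measurements.reset_index(drop=True)
        self.validate()

    @property
    def n(self) -> int:
        return len(self.subjects)

    def validate(self) -> None:
        sub = self.subjects
        meas = self.measurements
        if sub["subject_id"].duplicated().any():
            dups = sub.loc[sub["subject_id"].duplicated(), "subject_id"].tolist()
            raise DataError(f"duplicate subject rows: {dups}")
        if not (sub["event_time"] > 0).all():
            raise DataError("event_time must be > 0 for all subjects")
        if not sub["event"].isin([0, 1]).all():
            raise DataError("event must be 0/1")
        for col in ("sex", "addiction"):
            if not sub[col].isin([0, 1]).all():
                raise DataError(f"{col} must be 0/1")
        if not (sub["age"] > 0).all():
            raise DataError("age must be positive")
        unknown = set(meas["subject_id"]) - set(sub["subject_id"])
        if unknown:
            raise DataError(f"measurements reference unknown subject ids: {sorted(unknown)}")
        if (meas["time"] < 0).any():
            raise DataError("measurement times must be >= 0")
        if (meas["marker_raw"] < 0).any():
            raise DataError("marker_raw must be >= 0")
        # trailing records after the recorded event/censoring time are dropped,
        # not fatal: registry extracts often carry them
        merged = meas.merge(sub[["subject_id", "event_time"]], on="subject_id")
        late = merged["time"] > merged["event_time"] + 1e-12
        if late.any():
            ids = merged.loc[late, "subject_id"].unique().tolist()
            warnings.warn(
                f"dropped {int(late.sum())} measurement(s) after event_time for subjects {ids}",
                stacklevel=2,
            )
            self.measurements = meas.loc[~late.values].reset_index(drop=True)

    def measurements_for(self, subject_id) -> pd.DataFrame:
        return self.measurements[self.measurements["subject_id"] == subject_id]

    def covariates_for(self, subject_id) -> CovariateVector:
        row = self.subjects.loc[self.subjects["subject_id"] == subject_id].iloc[0]
        return CovariateVector(int(row["sex"]), int(row["addiction"]), float(row["age"]))

    def iter_subjects(self) -> Iterable[tuple[SurvivalRecord, CovariateVector]]:
        for _, row in self.subjects.iterrows():
            yield (
                SurvivalRecord(row["subject_id"], float(row["event_time"]), int(row["event"])),
                CovariateVector(int(row["sex"]), int(row["addiction"]), float(row["age"])),
            )


class FilterResult(NamedTuple):
    dataset: JointDataset
    excluded: pd.DataFrame  # subject_id, n_measurements, reason


def filter_eligible(dataset: JointDataset, min_measurements: int = 2) -> FilterResult:
    """Retain subjects with at least ``min_measurements`` biomarker measurements.

    Mirrors the cohort eligibility rule (listwise removal of subjects with
    fewer than two CD4 measurements).  Returns the filtered dataset and an
    exclusion report.  Idempotent.
    """
    counts = dataset.measurements.groupby("subject_id").size()
    counts = counts.reindex(dataset.subjects["subject_id"], fill_value=0)
    keep = counts >= min_measurements
    excluded = pd.DataFrame(
        {
            "subject_id": counts.index[~keep],
            "n_measurements": counts[~keep].values,
            "reason": [
                f"fewer than {min_measurements} measurements" for _ in range(int((~keep).sum()))
            ],
        }
    )
    kept_ids = set(counts.index[keep])
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        out = JointDataset(
            dataset.subjects[dataset.subjects["subject_id"].isin(kept_ids)].copy(),
            dataset.measurements[dataset.measurements["subject_id"].isin(kept_ids)].copy(),
            transform=dataset.transform,
        )
    return FilterResult(out, excluded)


def read_joint_data(
    measurements_path,
    subjects_path,
    transform: str = "fourth_root",
) -> JointDataset:
    """Read the two-CSV input format and build a validated :class:`JointDataset`.

    ``measurements.csv``: subject_id,time,cd4 — ``subjects.csv``:
    subject_id,event_time,event,sex,addiction,age.  Rows with missing or
    non-numeric required fields are rejected; each rejection is recorded in
    the returned dataset's ``report`` with its 1-based file line number.
    """
    report: list[str] = []

    sub_raw = pd.read_csv(subjects_path, dtype={"subject_id": str})
    missing = set(SUBJECT_COLUMNS) - set(sub_raw.columns)
    if missing:
        raise DataError(f"{subjects_path}: missing columns {sorted(missing)}")
    meas_raw = pd.read_csv(measurements_path, dtype={"subject_id": str})
    missing = set(MEASUREMENT_COLUMNS) - set(meas_raw.columns)
    if missing:
        raise DataError(f"{measurements_path}: missing columns {sorted(missing)}")

    def _clean(df: pd.DataFrame, numeric_cols: list[str], path) -> pd.DataFrame:
        ok = df["subject_id"].notna()
        coerced = {}
        for col in numeric_cols:
            vals = pd.to_numeric(df[col], errors="coerce")
            bad = vals.isna() & ok
            for idx in df.index[bad]:
                report.append(f"{path}:line {idx + 2}: invalid value in column '{col}'")
            ok &= vals.notna()
            coerced[col] = vals
        for idx in df.index[df["subject_id"].isna()]:
            report.append(f"{path}:line {idx + 2}: missing subject_id")
        out = df[ok].copy()
        for col, vals in coerced.items():
            out[col] = vals[ok]
        return out

    sub = _clean(sub_raw, ["event_time", "event", "sex", "addiction", "age"], subjects_path)
    meas = _clean(meas_raw, ["time", "cd4"], measurements_path)

    meas = meas.rename(columns={"cd4": "marker_raw"})
    meas["marker"] = transform_marker(meas["marker_raw"].to_numpy(), transform)
    ds = JointDataset(
        sub[SUBJECT_COLUMNS],
        meas[["subject_id", "time", "marker_raw", "marker"]],
        transform=transform,
        report=report,
    )
    return ds


def write_joint_data(dataset: JointDataset, measurements_path, subjects_path) -> None:
    """Write the canonical two-CSV dialect (full float precision round-trips)."""
    dataset.subjects[SUBJECT_COLUMNS].to_csv(subjects_path, index=False, float_format="%.17g")
    out = dataset.measurements.rename(columns={"marker_raw": "cd4"})
    out[["subject_id", "time", "cd4"]].to_csv(measurements_path, index=False, float_format="%.17g")


def summarize_cohort(dataset: JointDataset) -> dict:
    """Cohort descriptives: size, events, age/baseline-marker/visit distributions."""
    if dataset.n == 0:
        raise DataError("cannot summarize an empty dataset")
    sub = dataset.subjects
    meas = dataset.measurements
    events = int(sub["event"].sum())
    visits = meas.groupby("subject_id").size().reindex(sub["subject_id"], fill_value=0)
    baseline = (
        meas.sort_values("time").groupby("subject_id")["marker_raw"].first()
    ).reindex(sub["subject_id"])

    def _med_iqr(x) -> dict:
        x = pd.Series(x).dropna()
        q1, med, q3 = x.quantile([0.25, 0.5, 0.75])
        return {"median": float(med), "iqr": float(q3 - q1)}

    return {
        "n": int(dataset.n),
        "events": events,
        "event_pct": 100.0 * events / dataset.n,
        "age": _med_iqr(sub["age"]),
        "baseline_marker": _med_iqr(baseline),
        "visits_per_subject": _med_iqr(visits),
        "total_measurements": int(len(meas)),
    }


def write_summary(summary: dict, path) -> None:
    with open(path, "w") as fh:
        json.dump(summary, fh, indent=2)


@dataclass
class CohortArrays:
    """Per-subject sufficient statistics used by both model families.

    The longitudinal sub-models only need, per subject, the visit count and
    the moments (sum t, sum t^2, sum y, sum t*y, sum y^2) of the measurement
    rows, plus the covariate row and the survival outcome.  Every likelihood
    in the package is computed from these arrays, which makes model fitting
    independent of cohort storage layout.
    """

    ids: np.ndarray
    k: np.ndarray  # visits per subject
    St: np.ndarray
    Stt: np.ndarray
    Sy: np.ndarray
    Sty: np.ndarray
    Syy: np.ndarray
    X: np.ndarray  # (n, 3): sex, addiction, age
    T: np.ndarray
    delta: np.ndarray

    @property
    def n(self) -> int:
        return len(self.ids)

    @classmethod
    def from_dataset(cls, dataset: JointDataset, max_time: float | None = None) -> "CohortArrays":
        sub = dataset.subjects
        meas = dataset.measurements
        if max_time is not None:
            meas = meas[meas["time"] <= max_time]
        g = meas.assign(
            t=meas["time"],
            tt=meas["time"] ** 2,
            y=meas["marker"],
            ty=meas["time"] * meas["marker"],
            yy=meas["marker"] ** 2,
        ).groupby("subject_id")[["t", "tt", "y", "ty", "yy"]]
        sums = g.sum().reindex(sub["subject_id"], fill_value=0.0)
        counts = g.size().reindex(sub["subject_id"], fill_value=0)
        return cls(
            ids=sub["subject_id"].to_numpy(),
            k=counts.to_numpy(dtype=float),
            St=sums["t"].to_numpy(),
            Stt=sums["tt"].to_numpy(),
            Sy=sums["y"].to_numpy(),
            Sty=sums["ty"].to_numpy(),
            Syy=sums["yy"].to_numpy(),
            X=sub[["sex", "addiction", "age"]].to_numpy(dtype=float),
            T=sub["event_time"].to_numpy(dtype=float),
            delta=sub["event"].to_numpy(dtype=float),
        )
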