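"""Cohort data model and derived analysis variables.

Raw per-patient records (demographics, serum creatinine, blood pressure,
baseline proteinuria, Oxford MESTC grades, treatment flags, and a
longitudinal eGFR series) are transformed into the eleven analysis
variables of the path model:

* ``M, E, S, T, C`` — binary histology indicators (T and C collapse the
  ordinal grade to 0 vs >=1),
* ``UPE0c`` — baseline urine protein excretion (g/d), cohort-mean-centered,
* ``SReGFR0c`` — square root of baseline eGFR, cohort-mean-centered,
* ``MAPc01`` — mean arterial pressure dichotomized at the cohort mean,
* ``ST, RASB`` — treatment indicators (steroid therapy with/without
  tonsillectomy; renin-angiotensin system blockade),
* ``SLOPE`` — per-patient least-squares slope of eGFR over follow-up time
  (ml/min/1.73m2 per year), the renal-functional-decline outcome.

Records with any required variable missing are excluded (complete-case
analysis; the structural model needs complete rows), each with a single
primary exclusion reason.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "PatientRecord",
    "CohortTable",
    "ValidationError",
    "UnsupportedAgeError",
    "compute_egfr",
    "compute_map",
    "compute_slope",
    "build_analysis_table",
    "read_cohort_csv",
    "read_series_csv",
    "write_cohort_csv",
    "write_series_csv",
    "write_analysis_table",
]

#: Analysis-variable column order used throughout the package.
ANALYSIS_COLUMNS = [
    "M", "E", "S", "T", "C",
    "UPE0c", "SReGFR0c", "MAPc01", "ST", "RASB", "SLOPE",
]

#: Priority order for the single primary exclusion reason.
_EXCLUSION_PRIORITY = ["MESTC", "UPE0", "eGFR0", "MAP", "SLOPE"]


class ValidationError(ValueError):
    """Raised when an input value violates a documented precondition."""


class UnsupportedAgeError(ValidationError):
    """Adult eGFR equation requested for a patient younger than 20 years."""


@dataclass
class PatientRecord:
    """Raw clinical, histological, and treatment data for one patient.

    Any field may be ``None`` (missing).  ``egfr0`` allows a precomputed
    baseline eGFR to be supplied directly, which is required for patients
    younger than 20 years (the pediatric creatinine equation is out of
    scope) and permitted whenever serum creatinine is unavailable.
    """

    patient_id: str
    age: Optional[float] = None            # years
    female: Optional[bool] = None
    serum_creatinine: Optional[float] = None   # mg/dl
    systolic_bp: Optional[float] = None        # mmHg
    diastolic_bp: Optional[float] = None       # mmHg
    map_direct: Optional[float] = None         # mmHg, if pressures unavailable
    upe0: Optional[float] = None               # g/d at biopsy
    M: Optional[int] = None                    # {0,1}
    E: Optional[int] = None                    # {0,1}
    S: Optional[int] = None                    # {0,1}
    T: Optional[int] = None                    # {0,1,2}
    C: Optional[int] = None                    # {0,1,2}
    st_treated: Optional[bool] = None
    rasb_treated: Optional[bool] = None
    egfr0: Optional[float] = None              # ml/min/1.73m2, precomputed
    egfr_series: list = field(default_factory=list)  # [(months, egfr), ...]
    followup_months: Optional[float] = None

    def validate(self) -> None:
        """Check field-level invariants; raises :class:`ValidationError`."""
        if self.age is not None and self.age <= 0:
            raise ValidationError(f"{self.patient_id}: age must be positive")
        if self.serum_creatinine is not None and self.serum_creatinine <= 0:
            raise ValidationError(
                f"{self.patient_id}: serum creatinine must be positive")
        for name, hi in (("M", 1), ("E", 1), ("S", 1), ("T", 2), ("C", 2)):
            v = getattr(self, name)
            if v is not None and v not in range(hi + 1):
                raise ValidationError(
                    f"{self.patient_id}: grade {name}={v} outside 0..{hi}")
        if (self.systolic_bp is not None and self.diastolic_bp is not None
                and self.systolic_bp < self.diastolic_bp):
            raise ValidationError(
                f"{self.patient_id}: systolic below diastolic pressure")
        times = [t for t, _ in self.egfr_series]
        if any(b <= a for a, b in zip(times, times[1:])):
            raise ValidationError(
                f"{self.patient_id}: eGFR series times not strictly increasing")


@dataclass
class CohortTable:
    """The derived analysis table plus centering constants and exclusions.

    ``data`` holds one row per retained patient with the columns of
    ``ANALYSIS_COLUMNS`` (indexed by patient id).  ``centering`` stores the
    cohort means of UPE0, sqrt(eGFR0), and MAP that were subtracted, so the
    transform can be reapplied to the retained subset verbatim.
    """

    data: pd.DataFrame
    centering: dict
    exclusions: list  # [(patient_id, reason), ...]

    @property
    def n(self) -> int:
        return len(self.data)

    @property
    def n_excluded(self) -> int:
        return len(self.exclusions)


def compute_egfr(serum_creatinine: float, age: float, female: bool) -> float:
    """Baseline eGFR (ml/min/1.73 m2) from the Japanese adult equation.

    eGFR = 194 * sCr^-1.094 * age^-0.287, multiplied by 0.739 for women.
    Valid for ages >= 20 only; younger patients must supply a precomputed
    eGFR (``PatientRecord.egfr0``).
    """
    if serum_creatinine is None or serum_creatinine <= 0:
        raise ValidationError("serum creatinine must be positive")
    if age is None or age <= 0:
        raise ValidationError("age must be positive")
    if age < 20:
        raise UnsupportedAgeError(
            "adult eGFR equation is valid for age >= 20; "
            "supply a precomputed eGFR for younger patients")
    value = 194.0 * serum_creatinine ** -1.094 * age ** -0.287
    if female:
        value *= 0.739
    return value


def compute_map(systolic_bp: float, diastolic_bp: float) -> float:
    """Mean arterial pressure: diastolic plus one third of the pulse pressure."""
    if diastolic_bp is None or systolic_bp is None or diastolic_bp <= 0:
        raise ValidationError("blood pressures must be positive")
    if systolic_bp < diastolic_bp:
        raise ValidationError("systolic pressure below diastolic pressure")
    return diastolic_bp + (systolic_bp - diastolic_bp) / 3.0


def compute_slope(
    egfr_series: Sequence[tuple],
    min_points: int = 3,
) -> Optional[float]:
    """Least-squares slope of eGFR on time, in ml/min/1.73m2 per year.

    ``egfr_series`` is a sequence of ``(months_since_biopsy, egfr)`` pairs;
    time is converted to years before the regression.  Returns ``None``
    when fewer than ``min_points`` measurements are available (this drives
    the missing-outcome exclusion).
    """
    if len(egfr_series) < min_points:
        return None
    t = np.asarray([m for m, _ in egfr_series], dtype=float) / 12.0
    y = np.asarray([e for _, e in egfr_series], dtype=float)
    slope = np.polyfit(t, y, 1)[0]
    return float(slope)


def _baseline_egfr(rec: PatientRecord) -> Optional[float]:
    if rec.egfr0 is not None:
        return rec.egfr0
    if rec.serum_creatinine is None or rec.age is None or rec.female is None:
        return None
    if rec.age < 20:
        return None  # pediatric equation not reproduced; egfr0 required
    return compute_egfr(rec.serum_creatinine, rec.age, rec.female)


def _baseline_map(rec: PatientRecord) -> Optional[float]:
    if rec.systolic_bp is not None and rec.diastolic_bp is not None:
        return compute_map(rec.systolic_bp, rec.diastolic_bp)
    return rec.map_direct


def build_analysis_table(
    records: Sequence[PatientRecord],
    min_series_points: int = 3,
    centering: Optional[dict] = None,
) -> CohortTable:
    """Construct the analysis table from raw records.

    Applies complete-case exclusion (any required variable missing), computes
    baseline eGFR, MAP, and SLOPE, then centers UPE0 and sqrt(eGFR0) on the
    retained-cohort means and dichotomizes MAP at its cohort mean (value
    exactly at the mean codes as 0).  Pass ``centering`` to reuse previously
    stored constants instead of recomputing them (idempotent re-application).
    """
    if len(records) == 0:
        raise ValidationError("no input records")

    rows = []
    exclusions = []
    for rec in records:
        rec.validate()
        missing = []
        if any(getattr(rec, g) is None for g in ("M", "E", "S", "T", "C")):
            missing.append("MESTC")
        if rec.upe0 is None:
            missing.append("UPE0")
        egfr0 = _baseline_egfr(rec)
        if egfr0 is None:
            missing.append("eGFR0")
        map_value = _baseline_map(rec)
        if map_value is None:
            missing.append("MAP")
        slope = compute_slope(rec.egfr_series, min_points=min_series_points)
        if slope is None or not np.isfinite(slope):
            missing.append("SLOPE")
        if rec.st_treated is None or rec.rasb_treated is None:
            missing.append("treatment")
        if missing:
            primary = min(
                missing,
                key=lambda m: _EXCLUSION_PRIORITY.index(m)
                if m in _EXCLUSION_PRIORITY else len(_EXCLUSION_PRIORITY),
            )
            exclusions.append((rec.patient_id, f"missing:{primary}"))
            continue
        rows.append({
            "patient_id": rec.patient_id,
            "M": int(rec.M), "E": int(rec.E), "S": int(rec.S),
            "T": int(rec.T >= 1), "C": int(rec.C >= 1),
            "UPE0": float(rec.upe0),
            "SReGFR0": float(np.sqrt(egfr0)),
            "MAP": float(map_value),
            "ST": int(bool(rec.st_treated)),
            "RASB": int(bool(rec.rasb_treated)),
            "SLOPE": float(slope),
        })

    if not rows:
        raise ValidationError("all records excluded; empty retained cohort")

    df = pd.DataFrame(rows).set_index("patient_id")
    if centering is None:
        centering = {
            "UPE0_mean": float(df["UPE0"].mean()),
            "SReGFR0_mean": float(df["SReGFR0"].mean()),
            "MAP_mean": float(df["MAP"].mean()),
        }
    if df["MAP"].nunique() == 1:
        warnings.warn("all MAP values identical: dichotomization is degenerate")

    df["UPE0c"] = df["UPE0"] - centering["UPE0_mean"]
    df["SReGFR0c"] = df["SReGFR0"] - centering["SReGFR0_mean"]
    # tie rule: MAP exactly at the cohort mean codes as 0
    df["MAPc01"] = (df["MAP"] - centering["MAP_mean"] > 0).astype(int)
    out = df[ANALYSIS_COLUMNS].copy()
    return CohortTable(data=out, centering=centering, exclusions=exclusions)


# ---------------------------------------------------------------------------
# Delimited-text I/O
# ---------------------------------------------------------------------------

_COHORT_COLUMNS = [
    "patient_id", "age", "female", "serum_creatinine", "systolic_bp",
    "diastolic_bp", "map_direct", "upe0", "M", "E", "S", "T", "C",
    "st_treated", "rasb_treated", "egfr0", "followup_months",
]


def _opt(value, cast):
    if value is None or (isinstance(value, float) and np.isnan(value)) or value == "":
        return None
    return cast(value)


def read_cohort_csv(cohort_path, series_path=None) -> list:
    """Read patient records from a cohort CSV plus optional long-format series CSV.

    The cohort file has one row per patient with the documented header
    names; missing values are empty fields.  The series file has columns
    ``patient_id, months_since_biopsy, egfr``.
    """
    df = pd.read_csv(cohort_path, dtype={"patient_id": str})
    series: dict = {}
    if series_path is not None:
        sdf = pd.read_csv(series_path, dtype={"patient_id": str})
        sdf = sdf.sort_values(["patient_id", "months_since_biopsy"])
        for pid, grp in sdf.groupby("patient_id"):
            series[pid] = list(
                zip(grp["months_since_biopsy"].astype(float),
                    grp["egfr"].astype(float)))
    records = []
    for _, row in df.iterrows():
        records.append(PatientRecord(
            patient_id=str(row["patient_id"]),
            age=_opt(row.get("age"), float),
            female=_opt(row.get("female"), lambda v: bool(int(v))),
            serum_creatinine=_opt(row.get("serum_creatinine"), float),
            systolic_bp=_opt(row.get("systolic_bp"), float),
            diastolic_bp=_opt(row.get("diastolic_bp"), float),
            map_direct=_opt(row.get("map_direct"), float),
            upe0=_opt(row.get("upe0"), float),
            M=_opt(row.get("M"), int), E=_opt(row.get("E"), int),
            S=_opt(row.get("S"), int), T=_opt(row.get("T"), int),
            C=_opt(row.get("C"), int),
            st_treated=_opt(row.get("st_treated"), lambda v: bool(int(v))),
            rasb_treated=_opt(row.get("rasb_treated"), lambda v: bool(int(v))),
            egfr0=_opt(row.get("egfr0"), float),
            egfr_series=series.get(str(row["patient_id"]), []),
            followup_months=_opt(row.get("followup_months"), float),
        ))
    return records


def write_cohort_csv(records: Sequence[PatientRecord], cohort_path) -> None:
    rows = []
    for rec in records:
        rows.append({
            "patient_id": rec.patient_id,
            "age": rec.age,
            "female": None if rec.female is None else int(rec.female),
            "serum_creatinine": rec.serum_creatinine,
            "systolic_bp": rec.systolic_bp,
            "diastolic_bp": rec.diastolic_bp,
            "map_direct": rec.map_direct,
            "upe0": rec.upe0,
            "M": rec.M, "E": rec.E, "S": rec.S, "T": rec.T, "C": rec.C,
            "st_treated": None if rec.st_treated is None else int(rec.st_treated),
            "rasb_treated": None if rec.rasb_treated is None else int(rec.rasb_treated),
            "egfr0": rec.egfr0,
            "followup_months": rec.followup_months,
        })
    pd.DataFrame(rows, columns=_COHORT_COLUMNS).to_csv(cohort_path, index=False)


def write_series_csv(records: Sequence[PatientRecord], series_path) -> None:
    rows = []
    for rec in records:
        for months, egfr in rec.egfr_series:
            rows.append({"patient_id": rec.patient_id,
                         "months_since_biopsy": months, "egfr": egfr})
    pd.DataFrame(rows, columns=["patient_id", "months_since_biopsy", "egfr"]
                 ).to_csv(series_path, index=False)


def write_analysis_table(table: CohortTable, table_path, exclusion_path=None) -> None:
    """Write the analysis table, and optionally the exclusion log, as CSV."""
    table.data.to_csv(table_path)
    if exclusion_path is not None:
        pd.DataFrame(table.exclusions, columns=["patient_id", "reason"]
                     ).to_csv(exclusion_path, index=False)
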