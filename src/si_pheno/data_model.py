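"""Canonical in-memory schema for outpatient EMR extracts and CSV interchange.

The interchange format is three comma-delimited UTF-8 tables keyed by
``patient_id``:

* ``patients.csv``      - patient_id, birth_year, gender, documented_si_note
* ``diagnoses.csv``     - patient_id, date, icd10
* ``prescriptions.csv`` - patient_id, date, atc, molecule, dose_mg, days_supplied

Dates are ISO-8601. Reading sorts each patient's events by date, drops rows
with unparseable dates (counted in the load report) and deduplicates exact
repeat prescription rows.
"""

from __future__ import annotations

import dataclasses
import datetime as dt
import re
from pathlib import Path

import pandas as pd

from .config import DATE_MAX, DATE_MIN

GENDERS = ("female", "male", "unspecified")
ICD10_RE = re.compile(r"^[A-Z][0-9]{2}(\.[0-9A-Z]{1,2})?$")

PATIENT_COLUMNS = ["patient_id", "birth_year", "gender", "documented_si_note"]
DIAGNOSIS_COLUMNS = ["patient_id", "date", "icd10"]
PRESCRIPTION_COLUMNS = ["patient_id", "date", "atc", "molecule", "dose_mg", "days_supplied"]


class SchemaError(ValueError):
    """An interchange file does not match the documented schema."""


@dataclasses.dataclass(frozen=True)
class DiagnosisEvent:
    date: dt.date
    icd10: str

    def __post_init__(self) -> None:
        if not ICD10_RE.match(self.icd10):
            raise ValueError(f"malformed ICD-10 code: {self.icd10!r}")


@dataclasses.dataclass(frozen=True)
class PrescriptionEvent:
    date: dt.date
    atc: str
    molecule: str
    dose_mg: float | None = None
    days_supplied: int | None = None

    def __post_init__(self) -> None:
        if not self.atc:
            raise ValueError("atc must be non-empty")
        if self.dose_mg is not None and not self.dose_mg > 0:
            raise ValueError("dose_mg must be positive when present")
        if self.days_supplied is not None and not self.days_supplied > 0:
            raise ValueError("days_supplied must be positive when present")


@dataclasses.dataclass
class PatientRecord:
    """One patient's demographics plus date-ordered diagnosis/prescription events."""

    patient_id: str
    birth_year: int
    gender: str
    diagnoses: list[DiagnosisEvent] = dataclasses.field(default_factory=list)
    prescriptions: list[PrescriptionEvent] = dataclasses.field(default_factory=list)
    documented_si_note: bool = False

    def __post_init__(self) -> None:
        if not self.patient_id:
            raise ValueError("patient_id must be non-empty")
        if self.gender not in GENDERS:
            raise ValueError(f"gender must be one of {GENDERS}")
        self.diagnoses = sorted(self.diagnoses, key=lambda e: e.date)
        self.prescriptions = sorted(self.prescriptions, key=lambda e: (e.date, e.atc))
        for ev in list(self.diagnoses) + list(self.prescriptions):
            if not (DATE_MIN <= ev.date <= DATE_MAX):
                raise ValueError(f"event date out of range: {ev.date}")


@dataclasses.dataclass
class LoadReport:
    n_patients: int = 0
    n_diagnoses: int = 0
    n_prescriptions: int = 0
    n_dropped_bad_dates: int = 0
    n_deduplicated: int = 0


def _require_columns(df: pd.DataFrame, required: list[str], path) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing required column(s) {missing}")


def _parse_dates(df: pd.DataFrame) -> tuple[pd.DataFrame, int]:
    parsed = pd.to_datetime(df["date"], format="%Y-%m-%d", errors="coerce")
    bad = parsed.isna()
    df = df.loc[~bad].copy()
    df["date"] = parsed[~bad].dt.date
    return df, int(bad.sum())


def read_emr(
    patients_path, diagnoses_path, prescriptions_path, config=None
) -> tuple[list[PatientRecord], LoadReport]:
    """Read the three interchange tables into one PatientRecord per patient."""
    report = LoadReport()
    pat = pd.read_csv(patients_path, dtype={"patient_id": str})
    dx = pd.read_csv(diagnoses_path, dtype={"patient_id": str, "icd10": str})
    rx = pd.read_csv(
        prescriptions_path,
        dtype={"patient_id": str, "atc": str, "molecule": str},
    )
    _require_columns(pat, PATIENT_COLUMNS, patients_path)
    _require_columns(dx, DIAGNOSIS_COLUMNS, diagnoses_path)
    _require_columns(rx, PRESCRIPTION_COLUMNS, prescriptions_path)

    if pat["patient_id"].duplicated().any():
        raise SchemaError("duplicate patient_id rows in patients table")

    if len(dx):
        dx, bad_dx = _parse_dates(dx)
        report.n_dropped_bad_dates += bad_dx
    if len(rx):
        rx, bad_rx = _parse_dates(rx)
        report.n_dropped_bad_dates += bad_rx
        before = len(rx)
        rx = rx.drop_duplicates(subset=["patient_id", "date", "atc", "dose_mg"])
        report.n_deduplicated += before - len(rx)

    dx_by_pid: dict[str, list[DiagnosisEvent]] = {}
    for row in dx.itertuples(index=False):
        dx_by_pid.setdefault(row.patient_id, []).append(
            DiagnosisEvent(date=row.date, icd10=row.icd10)
        )
    rx_by_pid: dict[str, list[PrescriptionEvent]] = {}
    for row in rx.itertuples(index=False):
        rx_by_pid.setdefault(row.patient_id, []).append(
            PrescriptionEvent(
                date=row.date,
                atc=row.atc,
                molecule=str(row.molecule).lower(),
                dose_mg=None if pd.isna(row.dose_mg) else float(row.dose_mg),
                days_supplied=None if pd.isna(row.days_supplied) else int(row.days_supplied),
            )
        )

    records = []
    for row in pat.itertuples(index=False):
        records.append(
            PatientRecord(
                patient_id=row.patient_id,
                birth_year=int(row.birth_year),
                gender=str(row.gender),
                diagnoses=dx_by_pid.get(row.patient_id, []),
                prescriptions=rx_by_pid.get(row.patient_id, []),
                documented_si_note=bool(row.documented_si_note),
            )
        )
    report.n_patients = len(records)
    report.n_diagnoses = len(dx)
    report.n_prescriptions = len(rx)
    return records, report


def records_to_frames(
    records: list[PatientRecord],
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    pat_rows, dx_rows, rx_rows = [], [], []
    for r in records:
        pat_rows.append(
            {
                "patient_id": r.patient_id,
                "birth_year": r.birth_year,
                "gender": r.gender,
                "documented_si_note": r.documented_si_note,
            }
        )
        for d in r.diagnoses:
            dx_rows.append(
                {"patient_id": r.patient_id, "date": d.date.isoformat(), "icd10": d.icd10}
            )
        for p in r.prescriptions:
            rx_rows.append(
                {
                    "patient_id": r.patient_id,
                    "date": p.date.isoformat(),
                    "atc": p.atc,
                    "molecule": p.molecule,
                    "dose_mg": p.dose_mg,
                    "days_supplied": p.days_supplied,
                }
            )
    return (
        pd.DataFrame(pat_rows, columns=PATIENT_COLUMNS),
        pd.DataFrame(dx_rows, columns=DIAGNOSIS_COLUMNS),
        pd.DataFrame(rx_rows, columns=PRESCRIPTION_COLUMNS),
    )


def write_emr(records: list[PatientRecord], out_dir) -> dict[str, Path]:
    """Write records as the three interchange CSVs; round-trips with read_emr."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    pat, dx, rx = records_to_frames(records)
    paths = {
        "patients": out_dir / "patients.csv",
        "diagnoses": out_dir / "diagnoses.csv",
        "prescriptions": out_dir / "prescriptions.csv",
    }
    pat.to_csv(paths["patients"], index=False)
    dx.to_csv(paths["diagnoses"], index=False)
    rx.to_csv(paths["prescriptions"], index=False)
    return paths


def read_emr_dir(in_dir, config=None) -> tuple[list[PatientRecord], LoadReport]:
    in_dir = Path(in_dir)
    return read_emr(
        in_dir / "patients.csv",
        in_dir / "diagnoses.csv",
        in_dir / "prescriptions.csv",
        config,
    )
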