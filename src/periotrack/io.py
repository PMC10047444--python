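"""CSV readers/writers for the note and structured-diagnosis schemas.

Notes: ``patient_id,visit_date,text`` (ISO dates, RFC 4180 quoting via
pandas).  Diagnoses: one row per record with missing fields as empty strings
and multi-valued locations joined with ``;``.
"""

from __future__ import annotations

import datetime as _dt
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

from .change_classifier import PatientTimeline, build_timeline
from .diagnosis_model import DiseaseType, Extent, Onset, PDDiagnosis, Severity
from .pd_extractor import ClinicalNote

DIAGNOSIS_COLUMNS = [
    "patient_id", "diagnosis_date", "disease_type", "severity",
    "extent", "onset", "location", "source_text",
]


def read_notes(path) -> list[ClinicalNote]:
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    required = {"patient_id", "visit_date", "text"}
    if missing := required - set(df.columns):
        raise ValueError(f"notes CSV is missing columns: {sorted(missing)}")
    return [
        ClinicalNote(
            patient_id=row.patient_id,
            visit_date=_dt.date.fromisoformat(row.visit_date),
            text=row.text,
        )
        for row in df.itertuples()
    ]


def _opt(cls, value: str):
    return cls(value) if value else None


def diagnoses_to_frame(records: Iterable[PDDiagnosis]) -> pd.DataFrame:
    rows = [
        {
            "patient_id": d.patient_id,
            "diagnosis_date": d.diagnosis_date.isoformat(),
            "disease_type": d.disease_type.value if d.disease_type else "",
            "severity": d.severity.value if d.severity else "",
            "extent": d.extent.value if d.extent else "",
            "onset": d.onset.value if d.onset else "",
            "location": ";".join(d.location),
            "source_text": d.source_text,
        }
        for d in records
    ]
    return pd.DataFrame(rows, columns=DIAGNOSIS_COLUMNS)


def write_diagnoses(records: Iterable[PDDiagnosis], path) -> None:
    diagnoses_to_frame(records).to_csv(path, index=False)


def read_diagnoses(path, date_column: str = "diagnosis_date") -> list[PDDiagnosis]:
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    if date_column not in df.columns and "visit_date" in df.columns:
        date_column = "visit_date"
    out = []
    for row in df.itertuples():
        loc = getattr(row, "location", "")
        out.append(
            PDDiagnosis(
                patient_id=row.patient_id,
                diagnosis_date=_dt.date.fromisoformat(getattr(row, date_column)),
                disease_type=_opt(DiseaseType, row.disease_type),
                severity=_opt(Severity, row.severity) if row.disease_type else None,
                extent=_opt(Extent, row.extent) if row.disease_type else None,
                onset=_opt(Onset, row.onset) if row.disease_type else None,
                location=tuple(loc.split(";")) if loc else (),
                source_text=getattr(row, "source_text", ""),
            )
        )
    return out


def timelines_from_records(records: Sequence[PDDiagnosis]) -> list[PatientTimeline]:
    """Group records by patient and build date-ordered timelines."""
    by_patient: dict[str, list[PDDiagnosis]] = {}
    for r in records:
        by_patient.setdefault(r.patient_id, []).append(r)
    return [build_timeline(recs) for _, recs in sorted(by_patient.items())]
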