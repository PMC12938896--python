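"""Readers/writers for courses and reports.

JSON is the canonical course format (one object per course, field
names matching the domain types).  The CSV alternative is a convenience
projection over a directory of flat tables (``assessments.csv``,
``lesions.csv``, ``measurements.csv``, ``treatments.csv``,
``clinical.csv``) joined on patient/lesion/assessment ids.

Report JSON is written with sorted keys and floats rounded to six
significant digits so identical inputs yield byte-identical output.
"""

from __future__ import annotations

import json
import math
from pathlib import Path
from typing import Iterable, Optional, Union

import pandas as pd

from .course_model import (
    ClinicalObservation,
    CourseValidationError,
    Lesion,
    LesionMeasurement,
    Modality,
    PatientCourse,
    QualitativeState,
    SteroidState,
    TreatmentEvent,
    days_to_months,
    validate_course,
)
from .response_engine import AssessmentReport

__all__ = [
    "course_to_dict",
    "course_from_dict",
    "read_course",
    "write_course",
    "report_to_dict",
    "write_report",
]

PathLike = Union[str, Path]


# -- course <-> dict ----------------------------------------------------------


def course_to_dict(course: PatientCourse) -> dict:
    return {
        "patient_id": course.patient_id,
        "assessment_days": list(course.assessment_days),
        "lesions": [
            {
                "lesion_id": les.lesion_id,
                "first_seen_day": les.first_seen_day,
                "is_new_on_study": les.is_new_on_study,
            }
            for les in course.lesions
        ],
        "treatments": [
            {
                "treatment_id": tr.treatment_id,
                "modality": tr.modality.value,
                "start_day": tr.start_day,
                "targeted_lesion_ids": sorted(tr.targeted_lesion_ids),
            }
            for tr in course.treatments
        ],
        "measurements": [
            {
                "lesion_id": m.lesion_id,
                "assessment_index": m.assessment_index,
                "longest_diameter_mm": m.longest_diameter_mm,
                "perpendicular_diameter_mm": m.perpendicular_diameter_mm,
                "volume_mm3": m.volume_mm3,
                "present": m.present,
                "qualitative_state": m.qualitative_state.value,
            }
            for m in course.measurements
        ],
        "clinical": [
            {
                "assessment_index": obs.assessment_index,
                "kps": obs.kps,
                "bss": obs.bss,
                "steroid_state": obs.steroid_state.value,
                "decline_attributed_to_non_cns": obs.decline_attributed_to_non_cns,
            }
            for obs in course.clinical
        ],
    }


def course_from_dict(doc: dict) -> PatientCourse:
    try:
        return PatientCourse(
            patient_id=doc["patient_id"],
            assessment_days=[int(d) for d in doc["assessment_days"]],
            lesions=[
                Lesion(
                    lesion_id=l["lesion_id"],
                    first_seen_day=int(l.get("first_seen_day", 0)),
                    is_new_on_study=bool(l.get("is_new_on_study", False)),
                )
                for l in doc.get("lesions", [])
            ],
            treatments=[
                TreatmentEvent(
                    treatment_id=t["treatment_id"],
                    modality=Modality(t["modality"]),
                    start_day=int(t["start_day"]),
                    targeted_lesion_ids=frozenset(t.get("targeted_lesion_ids", [])),
                )
                for t in doc.get("treatments", [])
            ],
            measurements=[
                LesionMeasurement(
                    lesion_id=m["lesion_id"],
                    assessment_index=int(m["assessment_index"]),
                    longest_diameter_mm=float(m["longest_diameter_mm"]),
                    perpendicular_diameter_mm=_opt_float(m.get("perpendicular_diameter_mm")),
                    volume_mm3=_opt_float(m.get("volume_mm3")),
                    present=bool(m.get("present", True)),
                    qualitative_state=QualitativeState(m.get("qualitative_state", "stable")),
                )
                for m in doc.get("measurements", [])
            ],
            clinical=[
                ClinicalObservation(
                    assessment_index=int(c["assessment_index"]),
                    kps=_opt_int(c.get("kps")),
                    bss=_opt_int(c.get("bss")),
                    steroid_state=SteroidState(c.get("steroid_state", "none")),
                    decline_attributed_to_non_cns=bool(
                        c.get("decline_attributed_to_non_cns", False)
                    ),
                )
                for c in doc.get("clinical", [])
            ],
        )
    except KeyError as exc:
        raise ValueError(f"course document missing required field: {exc}") from exc


def _opt_float(value) -> Optional[float]:
    if value is None or (isinstance(value, float) and math.isnan(value)):
        return None
    return float(value)


def _opt_int(value) -> Optional[int]:
    if value is None or (isinstance(value, float) and math.isnan(value)):
        return None
    return int(value)


# -- course file I/O ----------------------------------------------------------

_CSV_SCHEMAS = {
    "assessments.csv": ["patient_id", "assessment_index", "day"],
    "lesions.csv": ["patient_id", "lesion_id", "first_seen_day", "is_new_on_study"],
    "measurements.csv": [
        "patient_id",
        "lesion_id",
        "assessment_index",
        "longest_diameter_mm",
        "perpendicular_diameter_mm",
        "volume_mm3",
        "present",
        "qualitative_state",
    ],
    "treatments.csv": [
        "patient_id",
        "treatment_id",
        "modality",
        "start_day",
        "targeted_lesion_ids",
    ],
    "clinical.csv": [
        "patient_id",
        "assessment_index",
        "kps",
        "bss",
        "steroid_state",
        "decline_attributed_to_non_cns",
    ],
}


def read_course(path: PathLike, fmt: Optional[str] = None) -> PatientCourse:
    """Read and validate a course from JSON (file) or CSV (directory)."""
    path = Path(path)
    if fmt is None:
        fmt = "csv" if path.is_dir() else "json"
    if fmt == "json":
        try:
            doc = json.loads(path.read_text())
        except json.JSONDecodeError as exc:
            raise ValueError(f"{path}: JSON parse failure at line {exc.lineno}: {exc.msg}")
        course = course_from_dict(doc)
    elif fmt == "csv":
        course = _read_course_csv(path)
    else:
        raise ValueError(f"unknown course format {fmt!r}")
    violations = validate_course(course)
    if violations:
        raise CourseValidationError(violations)
    return course


def _read_csv_table(path: Path, required: list[str]) -> pd.DataFrame:
    if not path.exists():
        raise ValueError(f"missing course table {path.name}")
    frame = pd.read_csv(path)
    missing = [col for col in required if col not in frame.columns]
    if missing:
        raise ValueError(f"{path.name}: missing required column(s) {missing}")
    return frame


def _read_course_csv(directory: Path) -> PatientCourse:
    tables = {
        name: _read_csv_table(directory / name, cols) for name, cols in _CSV_SCHEMAS.items()
    }
    assessments = tables["assessments.csv"].sort_values("assessment_index")
    patient_id = str(assessments["patient_id"].iloc[0])
    doc = {
        "patient_id": patient_id,
        "assessment_days": [int(d) for d in assessments["day"]],
        "lesions": tables["lesions.csv"].to_dict("records"),
        "treatments": [
            {
                **row,
                "targeted_lesion_ids": [
                    lid
                    for lid in str(row.get("targeted_lesion_ids") or "").split(";")
                    if lid and lid != "nan"
                ],
            }
            for row in tables["treatments.csv"].to_dict("records")
        ],
        "measurements": tables["measurements.csv"].to_dict("records"),
        "clinical": tables["clinical.csv"].to_dict("records"),
    }
    return course_from_dict(doc)


def write_course(course: PatientCourse, path: PathLike, fmt: Optional[str] = None) -> Path:
    """Write a course as canonical JSON or as the CSV directory projection."""
    path = Path(path)
    if fmt is None:
        fmt = "json" if path.suffix == ".json" else "csv" if path.suffix == "" else "json"
    if fmt == "json":
        path.parent.mkdir(parents=True, exist_ok=True)
        path.write_text(_dumps(course_to_dict(course)) + "\n")
        return path
    if fmt != "csv":
        raise ValueError(f"unknown course format {fmt!r}")
    path.mkdir(parents=True, exist_ok=True)
    pid = course.patient_id
    pd.DataFrame(
        {
            "patient_id": pid,
            "assessment_index": range(course.n_assessments),
            "day": course.assessment_days,
        }
    ).to_csv(path / "assessments.csv", index=False)
    doc = course_to_dict(course)
    pd.DataFrame([{"patient_id": pid, **l} for l in doc["lesions"]]).to_csv(
        path / "lesions.csv", index=False
    )
    treatments = [
        {
            "patient_id": pid,
            **{**t, "targeted_lesion_ids": ";".join(t["targeted_lesion_ids"])},
        }
        for t in doc["treatments"]
    ]
    pd.DataFrame(treatments, columns=_CSV_SCHEMAS["treatments.csv"]).to_csv(
        path / "treatments.csv", index=False
    )
    pd.DataFrame(
        [{"patient_id": pid, **m} for m in doc["measurements"]],
        columns=_CSV_SCHEMAS["measurements.csv"],
    ).to_csv(path / "measurements.csv", index=False)
    pd.DataFrame(
        [{"patient_id": pid, **c} for c in doc["clinical"]],
        columns=_CSV_SCHEMAS["clinical.csv"],
    ).to_csv(path / "clinical.csv", index=False)
    return path


# -- report serialization -----------------------------------------------------


def _round_floats(obj, sig: int = 6):
    if isinstance(obj, float):
        if obj == 0 or not math.isfinite(obj):
            return obj
        return float(f"{obj:.{sig}g}")
    if isinstance(obj, dict):
        return {k: _round_floats(v, sig) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_round_floats(v, sig) for v in obj]
    return obj


def _dumps(doc: dict) -> str:
    return json.dumps(_round_floats(doc), sort_keys=True, indent=1)


def report_to_dict(report: AssessmentReport) -> dict:
    dbf = report.dbf_summary
    return {
        "patient_id": report.patient_id,
        "policy": report.policy,
        "best_overall": report.best_overall.value if report.best_overall else None,
        "time_to_progression_days": report.time_to_progression_days,
        "mixed_response_fractions": dict(report.mixed_response_fractions),
        "discrepancy_flag": report.discrepancy_flag,
        "timepoints": [
            {
                "assessment_index": tp.assessment_index,
                "assessment_day": tp.assessment_day,
                "target_category": tp.target_category.value,
                "nontarget_state": tp.nontarget_state.value,
                "new_lesions_present": tp.new_lesions_present,
                "new_lesions_confirmed": tp.new_lesions_confirmed,
                "steroid_state": tp.steroid_state.value,
                "clinical_state": tp.clinical_state.value,
                "overall": tp.overall.value,
                "reasons": list(tp.reasons),
            }
            for tp in report.timepoints
        ],
        "lesions": [
            {
                "lesion_id": lr.lesion_id,
                "categories": [c.value for c in lr.categories],
                "final_category": lr.final_category.value,
                "lesion_baseline_mm": lr.lesion_baseline_mm,
                "lesion_nadir_mm": lr.lesion_nadir_mm,
            }
            for lr in report.lesions
        ],
        "designation": [
            {
                "assessment_index": e.assessment_index,
                "target_ids": list(e.target_ids),
                "nontarget_ids": sorted(e.nontarget_ids),
                "composition_changed": e.composition_changed,
                "baseline_sld_mm": e.baseline_sld_mm,
                "nadir_sld_mm": e.nadir_sld_mm,
            }
            for e in report.timeline.entries
        ],
        "dbf": {
            "reference_day": dbf.reference_day,
            "events": [
                {
                    "event_day": ev.event_day,
                    "assessment_index": ev.assessment_index,
                    "lesion_ids": sorted(ev.lesion_ids),
                    "count": ev.count,
                    "volume_mm3": ev.volume_mm3,
                    "confirmed": ev.confirmed,
                }
                for ev in dbf.events
            ],
            "total_new_lesions": dbf.total_new_lesions,
            "total_volume_mm3": dbf.total_volume_mm3,
            "latency_days": dbf.latency_days,
            "latency_months": (
                days_to_months(dbf.latency_days) if dbf.latency_days is not None else None
            ),
            "bmv_per_year": dbf.bmv_per_year,
            "vbmv_mm3_per_year": dbf.vbmv_mm3_per_year,
        },
        "audit_log": list(report.audit_log),
    }


def write_report(
    report: AssessmentReport,
    out_dir: PathLike,
    formats: Iterable[str] = ("json", "csv"),
) -> list[Path]:
    """Write the report; returns the paths written.

    ``json`` -> full structure (``report.json``); ``csv`` -> flat
    per-timepoint table (``timepoints.csv``) and DBF events
    (``dbf.csv``).  The audit log is always written (``audit.log``).
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written = []
    doc = report_to_dict(report)
    formats = set(formats)
    unknown = formats - {"json", "csv"}
    if unknown:
        raise ValueError(f"unknown report format(s): {sorted(unknown)}")
    if "json" in formats:
        target = out_dir / "report.json"
        target.write_text(_dumps(doc) + "\n")
        written.append(target)
    if "csv" in formats:
        target = out_dir / "timepoints.csv"
        pd.DataFrame(
            [
                {
                    "assessment_day": tp["assessment_day"],
                    "target_category": tp["target_category"],
                    "nontarget_state": tp["nontarget_state"],
                    "new_lesions": tp["new_lesions_confirmed"],
                    "steroids": tp["steroid_state"],
                    "clinical": tp["clinical_state"],
                    "overall": tp["overall"],
                }
                for tp in doc["timepoints"]
            ]
        ).to_csv(target, index=False)
        written.append(target)
        target = out_dir / "dbf.csv"
        pd.DataFrame(
            [
                {
                    "event_day": ev["event_day"],
                    "count": ev["count"],
                    "volume_mm3": ev["volume_mm3"],
                    "confirmed": ev["confirmed"],
                }
                for ev in doc["dbf"]["events"]
            ],
            columns=["event_day", "count", "volume_mm3", "confirmed"],
        ).to_csv(target, index=False)
        written.append(target)
    log = out_dir / "audit.log"
    log.write_text("\n".join(doc["audit_log"]) + "\n")
    written.append(log)
    return written
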