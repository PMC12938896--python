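"""Domain types, validation, and elementary geometry for longitudinal patient courses.

A :class:`PatientCourse` bundles everything known about one patient:
the imaging time grid (``assessment_days``), the lesions seen on study,
the treatments delivered, per-lesion size measurements at each
assessment, and clinical observations (KPS, BSS, corticosteroid state).

Time is modelled as integer day offsets from the baseline assessment
(index 0).  Months are reported as ``days / 30.44`` so that latency and
velocity metrics are reproducible.
"""

from __future__ import annotations

import math
from bisect import bisect_left
from dataclasses import dataclass, field
from enum import Enum
from typing import Optional

__all__ = [
    "DAYS_PER_MONTH",
    "DAYS_PER_YEAR",
    "QualitativeState",
    "Modality",
    "FOCAL_MODALITIES",
    "SteroidState",
    "LesionMeasurement",
    "Lesion",
    "TreatmentEvent",
    "ClinicalObservation",
    "PatientCourse",
    "validate_course",
    "sphere_volume_from_diameter",
    "measurement_volume_mm3",
    "days_to_months",
    "months_to_days",
]

DAYS_PER_MONTH = 30.44
DAYS_PER_YEAR = 365.25

VALID_KPS = frozenset(range(0, 101, 10))


def days_to_months(days: float) -> float:
    """Convert a day offset to months at the fixed 30.44 d/month rate."""
    return days / DAYS_PER_MONTH


def months_to_days(months: float) -> int:
    """Place a month offset on the integer day grid (nearest day)."""
    return round(months * DAYS_PER_MONTH)


class QualitativeState(str, Enum):
    """Radiologist's qualitative call for a lesion at one assessment."""

    STABLE = "stable"
    IMPROVED = "improved"
    UNEQUIVOCAL_PROGRESSION = "unequivocal_progression"
    ABSENT = "absent"
    NOT_ASSESSED = "not_assessed"


class Modality(str, Enum):
    SRS = "SRS"
    FSRT = "FSRT"
    WBRT = "WBRT"
    SURGERY = "surgery"
    SYSTEMIC = "systemic"


#: Modalities that act on an explicit set of lesions.
FOCAL_MODALITIES = frozenset({Modality.SRS, Modality.FSRT, Modality.SURGERY})


class SteroidState(str, Enum):
    NONE = "none"
    STABLE = "stable"
    DECREASED = "decreased"
    INCREASED = "increased"


@dataclass(frozen=True)
class LesionMeasurement:
    """Size of one lesion at one assessment.

    ``present=False`` records a disappeared lesion; it keeps its id and
    contributes 0 mm to diameter sums.
    """

    lesion_id: str
    assessment_index: int
    longest_diameter_mm: float
    perpendicular_diameter_mm: Optional[float] = None
    volume_mm3: Optional[float] = None
    present: bool = True
    qualitative_state: QualitativeState = QualitativeState.STABLE


@dataclass(frozen=True)
class Lesion:
    """An identified lesion; anatomy is deliberately not modelled."""

    lesion_id: str
    first_seen_day: int = 0
    is_new_on_study: bool = False


@dataclass(frozen=True)
class TreatmentEvent:
    """One delivered treatment.

    An empty ``targeted_lesion_ids`` set marks a non-focal treatment
    (WBRT or systemic) acting on all lesions.
    """

    treatment_id: str
    modality: Modality
    start_day: int
    targeted_lesion_ids: frozenset[str] = frozenset()

    def is_focal(self) -> bool:
        return self.modality in FOCAL_MODALITIES


@dataclass(frozen=True)
class ClinicalObservation:
    """Clinical status at one assessment (KPS and/or BSS required)."""

    assessment_index: int
    kps: Optional[int] = None
    bss: Optional[int] = None
    steroid_state: SteroidState = SteroidState.NONE
    decline_attributed_to_non_cns: bool = False


@dataclass
class PatientCourse:
    """All per-patient inputs for one assessment run."""

    patient_id: str
    assessment_days: list[int]
    lesions: list[Lesion] = field(default_factory=list)
    treatments: list[TreatmentEvent] = field(default_factory=list)
    measurements: list[LesionMeasurement] = field(default_factory=list)
    clinical: list[ClinicalObservation] = field(default_factory=list)

    # -- convenience accessors -------------------------------------------------

    @property
    def n_assessments(self) -> int:
        return len(self.assessment_days)

    def lesion_ids(self) -> list[str]:
        return [les.lesion_id for les in self.lesions]

    def measurement_map(self) -> dict[tuple[str, int], LesionMeasurement]:
        return {(m.lesion_id, m.assessment_index): m for m in self.measurements}

    def measurement(self, lesion_id: str, t: int) -> Optional[LesionMeasurement]:
        for m in self.measurements:
            if m.lesion_id == lesion_id and m.assessment_index == t:
                return m
        return None

    def first_assessment_index(self, lesion_id: str) -> int:
        """Index of the assessment at which the lesion is first on record.

        Derived from the lesion's ``first_seen_day`` (first assessment on
        or after that day); falls back to the earliest measurement.
        """
        for les in self.lesions:
            if les.lesion_id == lesion_id:
                idx = bisect_left(self.assessment_days, les.first_seen_day)
                return min(idx, self.n_assessments - 1)
        indices = [m.assessment_index for m in self.measurements if m.lesion_id == lesion_id]
        if not indices:
            raise KeyError(f"unknown lesion {lesion_id!r}")
        return min(indices)

    def clinical_at(self, t: int) -> Optional[ClinicalObservation]:
        for obs in self.clinical:
            if obs.assessment_index == t:
                return obs
        return None


# -- geometry -----------------------------------------------------------------


def sphere_volume_from_diameter(d_mm: float) -> float:
    """Volume (mm³) of a sphere with diameter ``d_mm``: π/6 · d³."""
    if d_mm < 0:
        raise ValueError(f"diameter must be non-negative, got {d_mm}")
    return math.pi / 6.0 * d_mm**3


def measurement_volume_mm3(m: LesionMeasurement) -> float:
    """Measured volume when supplied, else the sphere proxy from the LD."""
    if not m.present:
        return 0.0
    if m.volume_mm3 is not None:
        return m.volume_mm3
    return sphere_volume_from_diameter(m.longest_diameter_mm)


# -- validation ---------------------------------------------------------------


def validate_course(course: PatientCourse) -> list[str]:
    """Check every type invariant; return one message per violation.

    Side-effect free and idempotent; an empty list means the course is
    well formed.
    """
    violations: list[str] = []
    n = course.n_assessments

    if n == 0:
        violations.append("course has no assessments")
        return violations
    days = course.assessment_days
    for a, b in zip(days, days[1:]):
        if b <= a:
            violations.append(f"assessment_days not strictly increasing at {a} -> {b}")

    known = set()
    for les in course.lesions:
        if les.lesion_id in known:
            violations.append(f"lesion {les.lesion_id!r}: duplicate lesion_id")
        known.add(les.lesion_id)
        new = les.first_seen_day > days[0]
        if les.is_new_on_study != new:
            violations.append(
                f"lesion {les.lesion_id!r}: is_new_on_study={les.is_new_on_study} "
                f"inconsistent with first_seen_day={les.first_seen_day}"
            )

    for tr in course.treatments:
        extra = set(tr.targeted_lesion_ids) - known
        if extra:
            violations.append(
                f"treatment {tr.treatment_id!r}: unknown targeted lesions {sorted(extra)}"
            )
        if tr.is_focal() and not tr.targeted_lesion_ids:
            violations.append(
                f"treatment {tr.treatment_id!r}: focal modality {tr.modality.value} "
                "requires a non-empty targeted lesion set"
            )

    seen_pairs: set[tuple[str, int]] = set()
    for m in course.measurements:
        where = f"measurement ({m.lesion_id!r}, t={m.assessment_index})"
        if m.lesion_id not in known:
            violations.append(f"{where}: unknown lesion_id")
        if not 0 <= m.assessment_index < n:
            violations.append(
                f"{where}: assessment_index out of range (course has {n} assessments)"
            )
        if (m.lesion_id, m.assessment_index) in seen_pairs:
            violations.append(f"{where}: more than one measurement for this lesion/assessment")
        seen_pairs.add((m.lesion_id, m.assessment_index))
        if m.longest_diameter_mm < 0:
            violations.append(f"{where}: negative longest_diameter_mm")
        if m.perpendicular_diameter_mm is not None:
            if m.perpendicular_diameter_mm < 0:
                violations.append(f"{where}: negative perpendicular_diameter_mm")
            elif m.perpendicular_diameter_mm > m.longest_diameter_mm:
                violations.append(f"{where}: perpendicular diameter exceeds longest diameter")
        if m.volume_mm3 is not None and m.volume_mm3 < 0:
            violations.append(f"{where}: negative volume_mm3")
        if not m.present and m.longest_diameter_mm != 0:
            violations.append(f"{where}: present=False requires longest_diameter_mm=0")
        if m.lesion_id in known and 0 <= m.assessment_index < n:
            first = course.first_assessment_index(m.lesion_id)
            if m.assessment_index < first:
                violations.append(
                    f"{where}: measured before the lesion's first_seen_day assessment "
                    f"(index {first})"
                )

    seen_obs: set[int] = set()
    for obs in course.clinical:
        where = f"clinical observation at t={obs.assessment_index}"
        if not 0 <= obs.assessment_index < n:
            violations.append(f"{where}: assessment_index out of range")
        if obs.assessment_index in seen_obs:
            violations.append(f"{where}: duplicate observation for this assessment")
        seen_obs.add(obs.assessment_index)
        if obs.kps is None and obs.bss is None:
            violations.append(f"{where}: at least one of kps, bss must be present")
        if obs.kps is not None and obs.kps not in VALID_KPS:
            violations.append(f"{where}: kps must be one of 0,10,...,100, got {obs.kps}")
        if obs.bss is not None and not 0 <= obs.bss <= 5:
            violations.append(f"{where}: bss must be in 0..5, got {obs.bss}")
        if obs.bss == 5 and obs.assessment_index != n - 1:
            violations.append(f"{where}: bss=5 (death) allowed only at the terminal observation")

    return violations


class CourseValidationError(ValueError):
    """Raised by entry points that require a well-formed course."""

    def __init__(self, violations: list[str]):
        self.violations = violations
        super().__init__("invalid patient course:\n" + "\n".join(f"  - {v}" for v in violations))
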