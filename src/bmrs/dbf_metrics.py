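"""Distant-brain-failure (DBF) detection and extent/latency/velocity metrics.

A DBF event is the appearance of one or more new lesions at a single
assessment after the reference day.  Extent is the cumulative count and
volume of new lesions; latency is the mean inter-event interval
anchored at the reference day (equivalently, last-event time divided by
the number of events); BMV and vBMV are the count and volume rates per
year of follow-up.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

from .course_model import (
    DAYS_PER_YEAR,
    PatientCourse,
    measurement_volume_mm3,
)
from .designation import AssessmentConfig

__all__ = [
    "DBFEvent",
    "DBFSummary",
    "new_lesion_first_appearance",
    "confirmed_new_lesions",
    "detect_dbf_events",
    "dbf_extent",
    "dbf_latency",
    "bmv",
    "vbmv",
    "summarize_dbf",
]


@dataclass(frozen=True)
class DBFEvent:
    event_day: int
    assessment_index: int
    lesion_ids: frozenset[str]
    count: int
    volume_mm3: float
    confirmed: bool


@dataclass(frozen=True)
class DBFSummary:
    events: tuple[DBFEvent, ...]
    total_new_lesions: int
    total_volume_mm3: float
    latency_days: Optional[float]
    bmv_per_year: Optional[float]
    vbmv_mm3_per_year: Optional[float]
    reference_day: int


def new_lesion_first_appearance(course: PatientCourse, reference_day: int) -> dict[str, int]:
    """First-appearance assessment index of each lesion new after ``reference_day``.

    A lesion counts as new when its first *present* measurement falls at
    an assessment strictly after the reference day.
    """
    out: dict[str, int] = {}
    for les in course.lesions:
        indices = [
            m.assessment_index
            for m in course.measurements
            if m.lesion_id == les.lesion_id and m.present
        ]
        if not indices:
            continue
        first = min(indices)
        if course.assessment_days[first] > reference_day:
            out[les.lesion_id] = first
    return out


def confirmed_new_lesions(
    course: PatientCourse, cfg: AssessmentConfig, reference_day: Optional[int] = None
) -> dict[str, bool]:
    """Confirmation status of each new lesion.

    With ``require_new_lesion_confirmation`` a new lesion is confirmed
    iff it is still present at the next assessment; an appearance at the
    terminal assessment stays pending.  With confirmation disabled,
    appearance is confirmation.
    """
    if reference_day is None:
        reference_day = course.assessment_days[0]
    mmap = course.measurement_map()
    status: dict[str, bool] = {}
    for lid, first in new_lesion_first_appearance(course, reference_day).items():
        if not cfg.require_new_lesion_confirmation:
            status[lid] = True
            continue
        nxt = mmap.get((lid, first + 1))
        status[lid] = bool(nxt is not None and nxt.present)
    return status


def detect_dbf_events(
    course: PatientCourse, cfg: AssessmentConfig, reference_day: int
) -> list[DBFEvent]:
    """Group new-lesion appearances into per-assessment DBF events.

    Events are dated at first appearance; simultaneous new lesions merge
    into one event.  Unconfirmed lesions are dropped unless
    ``cfg.dbf_include_unconfirmed`` is set.
    """
    if reference_day not in course.assessment_days:
        raise ValueError(f"reference_day {reference_day} is not an assessment day")
    appearances = new_lesion_first_appearance(course, reference_day)
    confirmation = confirmed_new_lesions(course, cfg, reference_day)
    mmap = course.measurement_map()

    by_assessment: dict[int, list[str]] = {}
    for lid, first in appearances.items():
        if not confirmation[lid] and not cfg.dbf_include_unconfirmed:
            continue
        by_assessment.setdefault(first, []).append(lid)

    events = []
    for t in sorted(by_assessment):
        lids = sorted(by_assessment[t])
        volume = sum(measurement_volume_mm3(mmap[(lid, t)]) for lid in lids)
        events.append(
            DBFEvent(
                event_day=course.assessment_days[t],
                assessment_index=t,
                lesion_ids=frozenset(lids),
                count=len(lids),
                volume_mm3=volume,
                confirmed=all(confirmation[lid] for lid in lids),
            )
        )
    return events


def dbf_extent(events: list[DBFEvent]) -> tuple[int, float]:
    """Total new-lesion count and volume over all events."""
    return sum(e.count for e in events), sum(e.volume_mm3 for e in events)


def dbf_latency(events: list[DBFEvent], reference_day: int) -> Optional[float]:
    """Mean inter-event interval in days, anchored at the reference day.

    With boundaries (reference, event_1, ..., event_k) this equals
    ``(event_k_day - reference_day) / k``.  Undefined without events.
    """
    if not events:
        return None
    return (events[-1].event_day - reference_day) / len(events)


def _followup_years(reference_day: int, last_followup_day: int) -> float:
    interval = last_followup_day - reference_day
    if interval <= 0:
        raise ValueError(
            f"follow-up interval must be positive, got {interval} days"
        )
    return interval / DAYS_PER_YEAR


def bmv(total_new_lesions: int, reference_day: int, last_followup_day: int) -> float:
    """Brain-metastasis velocity: new lesions per year of follow-up."""
    return total_new_lesions / _followup_years(reference_day, last_followup_day)


def vbmv(total_volume_mm3: float, reference_day: int, last_followup_day: int) -> float:
    """Volumetric brain-metastasis velocity: new-lesion mm³ per year."""
    return total_volume_mm3 / _followup_years(reference_day, last_followup_day)


def summarize_dbf(
    course: PatientCourse,
    cfg: AssessmentConfig,
    reference_day: Optional[int] = None,
    last_followup_day: Optional[int] = None,
) -> DBFSummary:
    """Full DBF summary for one course relative to ``reference_day``."""
    if reference_day is None:
        reference_day = course.assessment_days[0]
    if last_followup_day is None:
        last_followup_day = course.assessment_days[-1]
    events = detect_dbf_events(course, cfg, reference_day)
    total, volume = dbf_extent(events)
    latency = dbf_latency(events, reference_day)
    if last_followup_day > reference_day:
        rate = bmv(total, reference_day, last_followup_day)
        vrate = vbmv(volume, reference_day, last_followup_day)
    else:
        rate = vrate = None
    return DBFSummary(
        events=tuple(events),
        total_new_lesions=total,
        total_volume_mm3=volume,
        latency_days=latency,
        bmv_per_year=rate,
        vbmv_mm3_per_year=vrate,
        reference_day=reference_day,
    )
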