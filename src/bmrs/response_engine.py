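"""Per-timepoint, per-lesion, and overall response classification.

The overall category at each assessment combines five components —
target-lesion change, non-target behaviour, new lesions,
corticosteroids, and clinical status.  Progression requires ANY of its
triggers; CR/PR/SD require ALL of the corresponding conditions.  The
engine additionally reports per-lesion categories, the mixed-response
fractions they induce, a discrepancy flag for courses where the
sum-based overall category conceals individual lesion behaviour, and a
DBF summary.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from enum import Enum
from typing import Optional

from .clinical_status import ClinicalState, clinical_state
from .course_model import (
    CourseValidationError,
    Lesion,
    PatientCourse,
    QualitativeState,
    SteroidState,
    validate_course,
)
from .dbf_metrics import (
    DBFSummary,
    confirmed_new_lesions,
    new_lesion_first_appearance,
    summarize_dbf,
)
from .designation import (
    AssessmentConfig,
    DesignationTimeline,
    PdRule,
    designate,
)

__all__ = [
    "Category",
    "NontargetState",
    "TimepointResponse",
    "LesionResponse",
    "AssessmentReport",
    "target_category",
    "lesion_category",
    "overall_response",
    "confirm_new_lesions",
    "assess_course",
    "windowed_assessment",
]


class Category(str, Enum):
    CR = "CR"
    PR = "PR"
    SD = "SD"
    PD = "PD"
    NE = "NE"


#: best-to-worst ordering used for best overall response
_CATEGORY_ORDER = [Category.CR, Category.PR, Category.SD, Category.PD]


class NontargetState(str, Enum):
    NONE = "none"
    STABLE_OR_IMPROVED = "stable_or_improved"
    UNEQUIVOCAL_PROGRESSION = "unequivocal_progression"
    NOT_ASSESSED = "not_assessed"


@dataclass(frozen=True)
class TimepointResponse:
    assessment_index: int
    assessment_day: int
    target_category: Category
    nontarget_state: NontargetState
    new_lesions_present: bool
    new_lesions_confirmed: bool
    steroid_state: SteroidState
    clinical_state: ClinicalState
    overall: Category
    reasons: tuple[str, ...]


@dataclass(frozen=True)
class LesionResponse:
    lesion_id: str
    categories: tuple[Category, ...]  # one per assessment; NE before first seen
    lesion_baseline_mm: float
    lesion_nadir_mm: float

    @property
    def final_category(self) -> Category:
        for cat in reversed(self.categories):
            if cat is not Category.NE:
                return cat
        return Category.NE


@dataclass
class AssessmentReport:
    patient_id: str
    policy: str
    timepoints: list[TimepointResponse]
    lesions: list[LesionResponse]
    timeline: DesignationTimeline
    best_overall: Optional[Category]
    time_to_progression_days: Optional[int]
    mixed_response_fractions: dict[str, float]
    discrepancy_flag: bool
    dbf_summary: DBFSummary
    audit_log: list[str] = field(default_factory=list)


# -- component classifiers ----------------------------------------------------


def _lesion_nadir(
    course: PatientCourse,
    timeline: DesignationTimeline,
    lesion_id: str,
    t: int,
) -> float:
    """Smallest LD of a target lesion since the last composition reset."""
    mmap = course.measurement_map()
    start = max(timeline[t].last_reset_index, course.first_assessment_index(lesion_id))
    values = []
    for s in range(start, t + 1):
        if lesion_id not in timeline[s].target_ids:
            continue
        m = mmap.get((lesion_id, s))
        if m is None:
            continue
        values.append(m.longest_diameter_mm if m.present else 0.0)
    return min(values) if values else 0.0


def target_category(
    timeline: DesignationTimeline,
    course: PatientCourse,
    t: int,
    cfg: AssessmentConfig,
) -> Category:
    """Target-lesion component at assessment ``t``.

    CR when every target lesion is absent; PD on the configured growth
    rule relative to nadir; PR on a >=30% SLD decrease from baseline;
    SD otherwise; NE with an empty target set.
    """
    entry = timeline[t]
    if not entry.target_ids:
        return Category.NE
    mmap = course.measurement_map()

    lds = {}
    all_absent = True
    for lid in entry.target_ids:
        m = mmap.get((lid, t))
        ld = m.longest_diameter_mm if (m is not None and m.present) else 0.0
        lds[lid] = ld
        if m is not None and m.present:
            all_absent = False
    if all_absent and t > 0:
        return Category.CR

    cur_sld = sum(lds.values())
    max_gain = max(
        lds[lid] - _lesion_nadir(course, timeline, lid, t) for lid in entry.target_ids
    )
    if cfg.pd_rule is PdRule.ABSOLUTE_2P5MM:
        is_pd = max_gain >= cfg.absolute_pd_mm
    else:
        sum_up = cur_sld >= (1.0 + cfg.pd_increase_frac) * entry.nadir_sld_mm
        is_pd = sum_up and max_gain >= cfg.pd_abs_increase_mm
    if is_pd:
        return Category.PD
    if cur_sld <= (1.0 - cfg.pr_decrease_frac) * entry.baseline_sld_mm:
        return Category.PR
    return Category.SD


def lesion_category(
    trajectory: list[tuple[float, bool]],
    cfg: AssessmentConfig,
) -> list[Category]:
    """Classify a single lesion's trajectory of ``(ld_mm, present)`` pairs.

    The same thresholds as the sum-based rule are applied to the single
    longest diameter; the lesion's own first measurement is its baseline
    and its running minimum its nadir.
    """
    if not trajectory:
        raise ValueError("lesion trajectory must contain at least one measurement")
    baseline = trajectory[0][0]
    categories: list[Category] = []
    nadir = None
    ever_present = False
    for ld, present in trajectory:
        value = ld if present else 0.0
        nadir = value if nadir is None else min(nadir, value)
        if not present:
            categories.append(Category.CR if ever_present else Category.NE)
            continue
        ever_present = True
        gain = value - nadir
        if cfg.pd_rule is PdRule.ABSOLUTE_2P5MM:
            is_pd = gain >= cfg.absolute_pd_mm
        else:
            is_pd = value >= (1.0 + cfg.pd_increase_frac) * nadir and gain >= cfg.pd_abs_increase_mm
        if is_pd:
            categories.append(Category.PD)
        elif value <= (1.0 - cfg.pr_decrease_frac) * baseline:
            categories.append(Category.PR)
        else:
            categories.append(Category.SD)
    return categories


def _nontarget_state(
    course: PatientCourse, timeline: DesignationTimeline, t: int
) -> NontargetState:
    mmap = course.measurement_map()
    any_present = False
    any_not_assessed = False
    for lid in sorted(timeline[t].nontarget_ids):
        m = mmap.get((lid, t))
        if m is None:
            any_not_assessed = True
            continue
        if not m.present:
            continue
        any_present = True
        if m.qualitative_state is QualitativeState.UNEQUIVOCAL_PROGRESSION:
            return NontargetState.UNEQUIVOCAL_PROGRESSION
        if m.qualitative_state is QualitativeState.NOT_ASSESSED:
            any_not_assessed = True
    if any_not_assessed:
        return NontargetState.NOT_ASSESSED
    if not any_present:
        return NontargetState.NONE
    return NontargetState.STABLE_OR_IMPROVED


_STEROIDS_OK_PR_SD = frozenset(
    {SteroidState.NONE, SteroidState.STABLE, SteroidState.DECREASED}
)


def overall_response(
    target: Category,
    nontarget: NontargetState,
    new_lesions_present: bool,
    new_lesions_confirmed: bool,
    steroid_state: SteroidState,
    clinical: ClinicalState,
    cfg: AssessmentConfig,
) -> tuple[Category, tuple[str, ...]]:
    """Combine the five components into the overall category.

    Returns the category together with the identifiers of the rules that
    fired (the audit trail).  PD requires ANY trigger; CR/PR/SD require
    ALL conditions of the corresponding column, else NE.
    """
    reasons = []
    if target is Category.PD:
        reasons.append("PD:target_growth")
    if nontarget is NontargetState.UNEQUIVOCAL_PROGRESSION:
        reasons.append("PD:nontarget_unequivocal_progression")
    if new_lesions_confirmed:
        reasons.append("PD:new_lesions_confirmed")
    if clinical is ClinicalState.WORSE:
        reasons.append("PD:clinical_worse")
    if reasons:
        return Category.PD, tuple(reasons)

    no_new = not new_lesions_present
    clin_ok = clinical is ClinicalState.STABLE_OR_IMPROVED
    nt_ok = nontarget in (NontargetState.NONE, NontargetState.STABLE_OR_IMPROVED)
    steroids_ok = steroid_state in _STEROIDS_OK_PR_SD

    if (
        target is Category.CR
        and nontarget is NontargetState.NONE
        and no_new
        and steroid_state is SteroidState.NONE
        and clin_ok
    ):
        return Category.CR, ("CR:all_conditions",)
    if target in (Category.CR, Category.PR) and nt_ok and no_new and steroids_ok and clin_ok:
        return Category.PR, ("PR:all_conditions",)
    if (
        target in (Category.CR, Category.PR, Category.SD)
        and nt_ok
        and no_new
        and steroids_ok
        and clin_ok
    ):
        return Category.SD, ("SD:all_conditions",)
    return Category.NE, ("NE:no_column_satisfied",)


def confirm_new_lesions(
    course: PatientCourse, cfg: AssessmentConfig
) -> dict[int, frozenset[str]]:
    """Confirmed new-lesion ids keyed by their first-appearance assessment."""
    status = confirmed_new_lesions(course, cfg)
    first = new_lesion_first_appearance(course, course.assessment_days[0])
    out: dict[int, set[str]] = {}
    for lid, confirmed in status.items():
        if confirmed:
            out.setdefault(first[lid], set()).add(lid)
    return {t: frozenset(s) for t, s in out.items()}


# -- course-level orchestration -----------------------------------------------


def assess_course(course: PatientCourse, cfg: AssessmentConfig) -> AssessmentReport:
    """Run designation, classify every timepoint and lesion, and summarize."""
    violations = validate_course(course)
    if violations:
        raise CourseValidationError(violations)

    timeline = designate(course, cfg)
    audit: list[str] = []
    for entry in timeline.entries:
        if entry.composition_changed:
            audit.append(
                f"t={entry.assessment_index} designation:composition_changed "
                f"targets={','.join(entry.target_ids)} reset baseline/nadir SLD to "
                f"{entry.baseline_sld_mm:.6g}"
            )

    appearance = new_lesion_first_appearance(course, course.assessment_days[0])
    confirmation = confirmed_new_lesions(course, cfg)

    timepoints: list[TimepointResponse] = []
    for t in range(course.n_assessments):
        tcat = target_category(timeline, course, t, cfg)
        ntstate = _nontarget_state(course, timeline, t)
        appearing = sorted(lid for lid, f in appearance.items() if f == t)
        confirmed_here = [lid for lid in appearing if confirmation.get(lid, False)]
        obs = course.clinical_at(t)
        steroids = obs.steroid_state if obs is not None else SteroidState.NONE
        clin = clinical_state(course.clinical, t, cfg)
        overall, reasons = overall_response(
            tcat, ntstate, bool(appearing), bool(confirmed_here), steroids, clin, cfg
        )
        timepoints.append(
            TimepointResponse(
                assessment_index=t,
                assessment_day=course.assessment_days[t],
                target_category=tcat,
                nontarget_state=ntstate,
                new_lesions_present=bool(appearing),
                new_lesions_confirmed=bool(confirmed_here),
                steroid_state=steroids,
                clinical_state=clin,
                overall=overall,
                reasons=reasons,
            )
        )
        audit.append(
            f"t={t} target={tcat.value} nontarget={ntstate.value} "
            f"new={'+'.join(appearing) if appearing else '-'} "
            f"steroids={steroids.value} clinical={clin.value} "
            f"overall={overall.value} reasons={';'.join(reasons)}"
        )

    lesions = _per_lesion_responses(course, cfg)

    post = [tp for tp in timepoints if tp.assessment_index > 0]
    achieved = [tp.overall for tp in post if tp.overall is not Category.NE]
    best = None
    for cat in _CATEGORY_ORDER:
        if cat in achieved:
            best = cat
            break

    ttp = next(
        (tp.assessment_day for tp in timepoints if tp.overall is Category.PD), None
    )

    finals = [lr.final_category for lr in lesions if lr.final_category is not Category.NE]
    fractions = {
        cat.value: finals.count(cat) / len(finals)
        for cat in Category
        if finals and finals.count(cat)
    }

    any_overall_pd = any(tp.overall is Category.PD for tp in timepoints)
    any_lesion_pd = Category.PD in finals
    responders = sum(1 for c in finals if c in (Category.CR, Category.PR))
    discrepancy = (not any_overall_pd and any_lesion_pd) or (
        any_overall_pd and finals and responders >= len(finals) / 2
    )
    if discrepancy:
        audit.append("course discrepancy_flag=true (per-lesion vs overall mismatch)")

    dbf = summarize_dbf(course, cfg)
    return AssessmentReport(
        patient_id=course.patient_id,
        policy=cfg.policy.value,
        timepoints=timepoints,
        lesions=lesions,
        timeline=timeline,
        best_overall=best,
        time_to_progression_days=ttp,
        mixed_response_fractions=fractions,
        discrepancy_flag=bool(discrepancy),
        dbf_summary=dbf,
        audit_log=audit,
    )


def _per_lesion_responses(
    course: PatientCourse, cfg: AssessmentConfig
) -> list[LesionResponse]:
    mmap = course.measurement_map()
    out = []
    for les in course.lesions:
        first = course.first_assessment_index(les.lesion_id)
        trajectory = []
        for t in range(first, course.n_assessments):
            m = mmap.get((les.lesion_id, t))
            if m is None:
                # gap in follow-up: carry absence of information as 'absent'
                trajectory.append((0.0, False))
            else:
                trajectory.append((m.longest_diameter_mm, m.present))
        if not trajectory:
            continue
        cats = [Category.NE] * first + lesion_category(trajectory, cfg)
        values = [ld if present else 0.0 for ld, present in trajectory]
        out.append(
            LesionResponse(
                lesion_id=les.lesion_id,
                categories=tuple(cats),
                lesion_baseline_mm=trajectory[0][0],
                lesion_nadir_mm=min(values),
            )
        )
    return out


def windowed_assessment(
    course: PatientCourse,
    window_start_day: int,
    window_end_day: Optional[int] = None,
    cfg: Optional[AssessmentConfig] = None,
) -> AssessmentReport:
    """Re-baseline the course at ``window_start_day`` and assess the window.

    Lesions present at the window start become the window's initial
    lesions; lesions first appearing inside the window are new.
    Treatments starting before the window are outside its scope and are
    dropped.
    """
    if cfg is None:
        cfg = AssessmentConfig()
    if window_start_day not in course.assessment_days:
        raise ValueError(
            f"window_start_day {window_start_day} is not an assessment day"
        )
    if window_end_day is None:
        window_end_day = course.assessment_days[-1]
    kept = [
        (i, day)
        for i, day in enumerate(course.assessment_days)
        if window_start_day <= day <= window_end_day
    ]
    if len(kept) < 2:
        raise ValueError("window must contain at least two assessments")
    index_map = {old: new for new, (old, _) in enumerate(kept)}
    new_days = [day - window_start_day for _, day in kept]

    mmap = course.measurement_map()
    lesions: list[Lesion] = []
    first_new_index: dict[str, int] = {}
    for les in course.lesions:
        present_at = [
            index_map[old]
            for old, _ in kept
            if (m := mmap.get((les.lesion_id, old))) is not None and m.present
        ]
        if not present_at:
            continue
        first = min(present_at)
        first_new_index[les.lesion_id] = first
        lesions.append(
            Lesion(
                lesion_id=les.lesion_id,
                first_seen_day=new_days[first],
                is_new_on_study=first > 0,
            )
        )
    kept_ids = {les.lesion_id for les in lesions}

    measurements = [
        replace(m, assessment_index=index_map[m.assessment_index])
        for m in course.measurements
        if m.assessment_index in index_map
        and m.lesion_id in kept_ids
        and index_map[m.assessment_index] >= first_new_index[m.lesion_id]
    ]
    treatments = []
    for tr in course.treatments:
        if tr.start_day < window_start_day:
            continue
        targeted = frozenset(tr.targeted_lesion_ids) & kept_ids
        if tr.is_focal() and not targeted:
            continue
        treatments.append(
            replace(tr, start_day=tr.start_day - window_start_day, targeted_lesion_ids=targeted)
        )
    clinical = [
        replace(obs, assessment_index=index_map[obs.assessment_index])
        for obs in course.clinical
        if obs.assessment_index in index_map
    ]
    sub = PatientCourse(
        patient_id=course.patient_id,
        assessment_days=new_days,
        lesions=lesions,
        treatments=treatments,
        measurements=measurements,
        clinical=clinical,
    )
    return assess_course(sub, cfg)
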