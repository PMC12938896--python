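"""Target/non-target lesion designation policies and SLD bookkeeping.

Three policies decide which lesions are measured quantitatively
("target") versus followed qualitatively ("non-target"):

* **A1** — up to ``max_targets`` measurable lesions are fixed at
  baseline; everything else, including lesions appearing later, stays
  non-target for the whole course.
* **A2** — starts as A1; a new measurable lesion is added while fewer
  than ``max_targets`` targets exist, otherwise it replaces the
  smallest current target if strictly larger.  Replaced lesions are
  followed qualitatively from then on.
* **A-Rx** — every treated lesion is target from the assessment at
  which its treatment's pre-treatment imaging is on record; there is no
  size threshold and no cap.

Whenever the target-set composition changes (A2, A-Rx), the baseline
and nadir sums of longest diameters (SLD) are re-seeded from the
current assessment.
"""

from __future__ import annotations

from bisect import bisect_right
from dataclasses import dataclass, fields
from enum import Enum

from .course_model import (
    FOCAL_MODALITIES,
    LesionMeasurement,
    PatientCourse,
)

__all__ = [
    "Policy",
    "PdRule",
    "StatusMetric",
    "AssessmentConfig",
    "DesignationEntry",
    "DesignationTimeline",
    "is_measurable",
    "designate",
    "designate_a1",
    "designate_a2",
    "designate_arx",
    "sld",
]


class Policy(str, Enum):
    A1 = "a1"
    A2 = "a2"
    ARX = "arx"


class PdRule(str, Enum):
    #: sum +20% over nadir AND one lesion +5 mm over its nadir
    RELATIVE_20PCT = "relative_20pct"
    #: one lesion +2.5 mm (absolute) over its nadir
    ABSOLUTE_2P5MM = "absolute_2p5mm"


class StatusMetric(str, Enum):
    KPS = "kps"
    BSS = "bss"
    BOTH = "both"


@dataclass(frozen=True)
class AssessmentConfig:
    """Thresholds and switches governing one assessment run."""

    measurable_longest_mm: float = 10.0
    measurable_perp_mm: float = 5.0
    max_targets: int = 5
    pr_decrease_frac: float = 0.30
    pd_increase_frac: float = 0.20
    pd_abs_increase_mm: float = 5.0
    pd_rule: PdRule = PdRule.RELATIVE_20PCT
    absolute_pd_mm: float = 2.5
    require_new_lesion_confirmation: bool = True
    bss_worsen_delta: int = 1
    policy: Policy = Policy.A1
    status_metric: StatusMetric = StatusMetric.BOTH
    dbf_include_unconfirmed: bool = False

    def __post_init__(self) -> None:
        for name in (
            "measurable_longest_mm",
            "measurable_perp_mm",
            "pd_abs_increase_mm",
            "absolute_pd_mm",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if self.max_targets < 1:
            raise ValueError("max_targets must be a positive integer")
        if not 0 < self.pr_decrease_frac < 1:
            raise ValueError("pr_decrease_frac must be in (0, 1)")
        if not 0 < self.pd_increase_frac < 1:
            raise ValueError("pd_increase_frac must be in (0, 1)")
        if self.bss_worsen_delta < 1:
            raise ValueError("bss_worsen_delta must be a positive integer")

    @classmethod
    def from_mapping(cls, mapping: dict) -> "AssessmentConfig":
        """Build from a plain dict (e.g. parsed YAML); unknown keys rejected."""
        valid = {f.name for f in fields(cls)}
        unknown = set(mapping) - valid
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        kwargs = dict(mapping)
        if "policy" in kwargs:
            kwargs["policy"] = Policy(str(kwargs["policy"]).lower())
        if "pd_rule" in kwargs:
            kwargs["pd_rule"] = PdRule(kwargs["pd_rule"])
        if "status_metric" in kwargs:
            kwargs["status_metric"] = StatusMetric(kwargs["status_metric"])
        return cls(**kwargs)


@dataclass(frozen=True)
class DesignationEntry:
    """Target/non-target membership and SLD state at one assessment."""

    assessment_index: int
    target_ids: tuple[str, ...]
    nontarget_ids: frozenset[str]
    composition_changed: bool
    baseline_sld_mm: float
    nadir_sld_mm: float
    #: assessment index at which the current baseline/nadir were seeded
    last_reset_index: int


@dataclass
class DesignationTimeline:
    policy: Policy
    entries: list[DesignationEntry]

    def __getitem__(self, t: int) -> DesignationEntry:
        return self.entries[t]

    def __len__(self) -> int:
        return len(self.entries)

    @property
    def reset_indices(self) -> list[int]:
        return [e.assessment_index for e in self.entries if e.composition_changed]


def is_measurable(m: LesionMeasurement, cfg: AssessmentConfig) -> bool:
    """Measurable disease test: LD and (if recorded) perpendicular diameter."""
    if not m.present:
        raise ValueError(f"is_measurable called on absent lesion {m.lesion_id!r}")
    if m.longest_diameter_mm < cfg.measurable_longest_mm:
        return False
    if m.perpendicular_diameter_mm is not None:
        return m.perpendicular_diameter_mm >= cfg.measurable_perp_mm
    return True


# -- internal helpers ---------------------------------------------------------


def _ld_at(mmap: dict, lesion_id: str, t: int) -> float:
    m = mmap.get((lesion_id, t))
    if m is None or not m.present:
        return 0.0
    return m.longest_diameter_mm


def _sum_ld(mmap: dict, target_ids: tuple[str, ...], t: int) -> float:
    return sum(_ld_at(mmap, lid, t) for lid in target_ids)


def _seen_by(course: PatientCourse, t: int) -> set[str]:
    return {
        les.lesion_id
        for les in course.lesions
        if course.first_assessment_index(les.lesion_id) <= t
    }


def _baseline_targets(course: PatientCourse, cfg: AssessmentConfig) -> tuple[str, ...]:
    """Largest measurable baseline lesions, up to the cap; ties by lesion_id."""
    mmap = course.measurement_map()
    candidates = []
    for les in course.lesions:
        m = mmap.get((les.lesion_id, 0))
        if m is None or not m.present:
            continue
        if is_measurable(m, cfg):
            candidates.append((-m.longest_diameter_mm, les.lesion_id))
    candidates.sort()
    return tuple(lid for _, lid in candidates[: cfg.max_targets])


def _finalize(
    policy: Policy,
    course: PatientCourse,
    targets_per_t: list[tuple[str, ...]],
) -> DesignationTimeline:
    """Derive composition changes, baseline/nadir SLD, and reset markers."""
    mmap = course.measurement_map()
    entries: list[DesignationEntry] = []
    baseline = nadir = 0.0
    last_reset = 0
    for t, targets in enumerate(targets_per_t):
        seen = _seen_by(course, t)
        nontargets = frozenset(seen - set(targets))
        cur_sld = _sum_ld(mmap, targets, t)
        changed = t > 0 and set(targets) != set(targets_per_t[t - 1])
        if t == 0 or changed:
            baseline = nadir = cur_sld
            last_reset = t
        else:
            nadir = min(nadir, cur_sld)
        entries.append(
            DesignationEntry(
                assessment_index=t,
                target_ids=targets,
                nontarget_ids=nontargets,
                composition_changed=changed,
                baseline_sld_mm=baseline,
                nadir_sld_mm=nadir,
                last_reset_index=last_reset,
            )
        )
    return DesignationTimeline(policy=policy, entries=entries)


# -- policies -----------------------------------------------------------------


def designate_a1(course: PatientCourse, cfg: AssessmentConfig) -> DesignationTimeline:
    """Fixed baseline target set; all later lesions are non-target."""
    targets = _baseline_targets(course, cfg)
    return _finalize(Policy.A1, course, [targets] * course.n_assessments)


def designate_a2(course: PatientCourse, cfg: AssessmentConfig) -> DesignationTimeline:
    """Baseline targets with add/replace of new measurable lesions.

    A new measurable lesion is added while the target count is below the
    cap; at the cap it replaces the smallest current target when strictly
    larger at the current assessment.  Simultaneous new lesions are
    processed largest first.  Replaced lesions stay non-target.
    """
    mmap = course.measurement_map()
    targets: list[str] = list(_baseline_targets(course, cfg))
    targets_per_t: list[tuple[str, ...]] = [tuple(targets)]

    for t in range(1, course.n_assessments):
        new_here = []
        for les in course.lesions:
            if course.first_assessment_index(les.lesion_id) != t:
                continue
            m = mmap.get((les.lesion_id, t))
            if m is not None and m.present and is_measurable(m, cfg):
                new_here.append((-m.longest_diameter_mm, les.lesion_id))
        new_here.sort()  # largest first; ties by lesion_id
        for neg_ld, new_id in new_here:
            new_ld = -neg_ld
            if len(targets) < cfg.max_targets:
                targets.append(new_id)
                continue
            # victim: smallest current LD; ties -> lexicographically greatest id
            victim = min(targets, key=lambda lid: (_ld_at(mmap, lid, t), _neg_key(lid)))
            if new_ld > _ld_at(mmap, victim, t):
                # replaced target moves to non-target for the rest of the course
                targets[targets.index(victim)] = new_id
        targets_per_t.append(tuple(targets))
    return _finalize(Policy.A2, course, targets_per_t)


def _neg_key(s: str) -> tuple[int, ...]:
    # inverts lexicographic order so min() picks the greatest id on ties
    return tuple(-ord(c) for c in s)


def designate_arx(course: PatientCourse, cfg: AssessmentConfig) -> DesignationTimeline:
    """Treatment-based designation: treated lesions are target.

    A focal treatment makes its targeted lesions target from the last
    assessment on or before the treatment start (the pre-treatment
    imaging).  A non-focal treatment (empty targeted set) covers every
    lesion present at its start plus lesions appearing while it is
    ongoing (until the next non-focal treatment begins).
    """
    days = course.assessment_days
    nonfocal = sorted(
        (tr for tr in course.treatments if not tr.targeted_lesion_ids),
        key=lambda tr: tr.start_day,
    )
    target_from: dict[str, int] = {}

    def _effective_index(start_day: int) -> int:
        idx = bisect_right(days, start_day) - 1
        return max(idx, 0)

    for tr in course.treatments:
        eff = _effective_index(tr.start_day)
        if tr.targeted_lesion_ids:
            covered = set(tr.targeted_lesion_ids)
        else:
            later = [o.start_day for o in nonfocal if o.start_day > tr.start_day]
            end_day = later[0] if later else None
            covered = {
                les.lesion_id
                for les in course.lesions
                if end_day is None or les.first_seen_day < end_day
            }
        for lid in covered:
            first = course.first_assessment_index(lid)
            start = max(eff, first)
            target_from[lid] = min(target_from.get(lid, start), start)

    targets_per_t: list[tuple[str, ...]] = []
    for t in range(course.n_assessments):
        members = [
            (start, lid) for lid, start in target_from.items() if start <= t
        ]
        members.sort()
        targets_per_t.append(tuple(lid for _, lid in members))
    return _finalize(Policy.ARX, course, targets_per_t)


_POLICY_DISPATCH = {
    Policy.A1: designate_a1,
    Policy.A2: designate_a2,
    Policy.ARX: designate_arx,
}


def designate(course: PatientCourse, cfg: AssessmentConfig) -> DesignationTimeline:
    """Run the designation policy selected by ``cfg.policy``."""
    return _POLICY_DISPATCH[cfg.policy](course, cfg)


def sld(course: PatientCourse, timeline: DesignationTimeline, t: int) -> float:
    """Sum of longest diameters over the target set at assessment ``t``."""
    if not 0 <= t < len(timeline.entries):
        raise IndexError(f"assessment index {t} out of range")
    return _sum_ld(course.measurement_map(), timeline[t].target_ids, t)
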