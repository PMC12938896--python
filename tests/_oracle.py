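"""Independent brute-force response oracle and random-course generator.

The oracle re-evaluates the five-component response grid directly from
the raw measurements with plain loops, sharing no code with the engine.
It assumes the fixed-baseline (A1) designation: up to five largest
measurable baseline lesions are target for the whole course.
"""

from __future__ import annotations

import numpy as np

from bmrs import (
    ClinicalObservation,
    Lesion,
    LesionMeasurement,
    Modality,
    PatientCourse,
    QualitativeState,
    SteroidState,
    TreatmentEvent,
)

STEROID_CHOICES = [s for s in SteroidState]
QUAL_CHOICES = [
    QualitativeState.STABLE,
    QualitativeState.STABLE,
    QualitativeState.STABLE,
    QualitativeState.IMPROVED,
    QualitativeState.UNEQUIVOCAL_PROGRESSION,
]


def random_course(rng: np.random.Generator) -> PatientCourse:
    """Small random course: <=4 measurable baseline lesions, <=6 assessments."""
    n_lesions = int(rng.integers(1, 5))
    n_assessments = int(rng.integers(3, 7))
    days = [int(91 * t) for t in range(n_assessments)]

    lesions, measurements = [], []
    for i in range(n_lesions):
        lid = f"L{i + 1}"
        lesions.append(Lesion(lesion_id=lid, first_seen_day=0))
        ld = float(rng.uniform(10, 40))
        absent = False
        for t in range(n_assessments):
            if t > 0 and not absent:
                ld = max(0.0, ld + float(rng.uniform(-8, 8)))
                if ld < 2.0:
                    absent = True
            if absent:
                measurements.append(
                    LesionMeasurement(lid, t, 0.0, present=False,
                                      qualitative_state=QualitativeState.ABSENT)
                )
            else:
                measurements.append(LesionMeasurement(lid, t, round(ld, 1)))

    # occasionally one new lesion that persists to the end
    if n_assessments > 2 and rng.random() < 0.4:
        t_new = int(rng.integers(1, n_assessments))
        size = round(float(rng.uniform(4, 15)), 1)
        qual = QUAL_CHOICES[int(rng.integers(len(QUAL_CHOICES)))]
        lesions.append(
            Lesion(lesion_id="NEW", first_seen_day=days[t_new], is_new_on_study=True)
        )
        for t in range(t_new, n_assessments):
            measurements.append(
                LesionMeasurement("NEW", t, size, qualitative_state=qual)
            )

    clinical = []
    for t in range(n_assessments):
        clinical.append(
            ClinicalObservation(
                assessment_index=t,
                kps=int(rng.choice([100, 90, 80, 70, 60, 50])),
                bss=int(rng.integers(0, 4)),
                steroid_state=STEROID_CHOICES[int(rng.integers(len(STEROID_CHOICES)))],
                decline_attributed_to_non_cns=bool(rng.random() < 0.3),
            )
        )
    return PatientCourse(
        patient_id=f"rand-{rng.integers(1 << 30)}",
        assessment_days=days,
        lesions=lesions,
        treatments=[
            TreatmentEvent(
                "T1", Modality.SRS, 0,
                frozenset(les.lesion_id for les in lesions if les.first_seen_day == 0),
            )
        ],
        measurements=measurements,
        clinical=clinical,
    )


def oracle_overall(course: PatientCourse, require_confirmation: bool = True) -> list[str]:
    """Per-timepoint overall category, evaluated naively from first principles."""
    n = len(course.assessment_days)
    meas = {(m.lesion_id, m.assessment_index): m for m in course.measurements}

    # A1 designation: five largest measurable baseline lesions
    baseline = []
    for les in course.lesions:
        m = meas.get((les.lesion_id, 0))
        if m is None or not m.present:
            continue
        measurable = m.longest_diameter_mm >= 10 and (
            m.perpendicular_diameter_mm is None or m.perpendicular_diameter_mm >= 5
        )
        if measurable:
            baseline.append((-m.longest_diameter_mm, les.lesion_id))
    baseline.sort()
    targets = [lid for _, lid in baseline[:5]]

    def ld(lid, t):
        m = meas.get((lid, t))
        return m.longest_diameter_mm if m is not None and m.present else 0.0

    slds = [sum(ld(lid, t) for lid in targets) for t in range(n)]

    # new lesions: first present appearance after baseline
    first_seen = {}
    for les in course.lesions:
        ts = [m.assessment_index for m in course.measurements
              if m.lesion_id == les.lesion_id and m.present]
        if ts and min(ts) > 0:
            first_seen[les.lesion_id] = min(ts)

    overall = []
    for t in range(n):
        # target component
        if not targets:
            tcat = "NE"
        else:
            present_any = any(
                (m := meas.get((lid, t))) is not None and m.present for lid in targets
            )
            if not present_any and t > 0:
                tcat = "CR"
            else:
                nadir_sld = min(slds[: t + 1])
                gains = []
                for lid in targets:
                    lesion_nadir = min(ld(lid, s) for s in range(t + 1))
                    gains.append(ld(lid, t) - lesion_nadir)
                if slds[t] >= 1.2 * nadir_sld and max(gains) >= 5.0:
                    tcat = "PD"
                elif slds[t] <= 0.7 * slds[0]:
                    tcat = "PR"
                else:
                    tcat = "SD"

        # non-target component
        nt = "none"
        nt_present = False
        for les in course.lesions:
            if les.lesion_id in targets:
                continue
            m = meas.get((les.lesion_id, t))
            if m is None:
                if any(mm.lesion_id == les.lesion_id and mm.assessment_index <= t
                       for mm in course.measurements):
                    nt = "not_assessed"
                continue
            if not m.present:
                continue
            nt_present = True
            if m.qualitative_state is QualitativeState.UNEQUIVOCAL_PROGRESSION:
                nt = "progression"
                break
            if m.qualitative_state is QualitativeState.NOT_ASSESSED:
                nt = "not_assessed"
        if nt == "none" and nt_present:
            nt = "stable"

        # new lesions at this assessment
        appearing = [lid for lid, f in first_seen.items() if f == t]
        confirmed = []
        for lid in appearing:
            if not require_confirmation:
                confirmed.append(lid)
            else:
                nxt = meas.get((lid, t + 1))
                if nxt is not None and nxt.present:
                    confirmed.append(lid)

        # clinical + steroids
        obs = next((o for o in course.clinical if o.assessment_index == t), None)
        ref = next((o for o in sorted(course.clinical, key=lambda o: o.assessment_index)), None)
        steroid = obs.steroid_state if obs else SteroidState.NONE
        worse = False
        if obs is not None and ref is not None and not obs.decline_attributed_to_non_cns:
            if obs.kps is not None and ref.kps is not None:
                b, c = ref.kps, obs.kps
                if (b >= 90 and c <= 70) or (b <= 80 and b - c >= 20) or c <= 50:
                    worse = True
            if obs.bss is not None and ref.bss is not None and obs.bss - ref.bss >= 1:
                worse = True

        if tcat == "PD" or nt == "progression" or confirmed or worse:
            overall.append("PD")
            continue
        steroids_ok = steroid in (SteroidState.NONE, SteroidState.STABLE, SteroidState.DECREASED)
        common = not appearing and not worse and nt in ("none", "stable")
        if tcat == "CR" and nt == "none" and common and steroid is SteroidState.NONE:
            overall.append("CR")
        elif tcat in ("CR", "PR") and common and steroids_ok:
            overall.append("PR")
        elif tcat in ("CR", "PR", "SD") and common and steroids_ok:
            overall.append("SD")
        else:
            overall.append("NE")
    return overall
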