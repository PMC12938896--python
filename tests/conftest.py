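import pytest

from bmrs import (
    AssessmentConfig,
    ClinicalObservation,
    Lesion,
    LesionMeasurement,
    Modality,
    PatientCourse,
    TreatmentEvent,
)


@pytest.fixture
def cfg():
    return AssessmentConfig()


def make_course(trajectories, days=None, treatments=None, clinical=None, patient_id="p"):
    """Compact course builder.

    ``trajectories`` maps lesion id to a list of longest diameters, one
    per assessment from baseline; ``None`` marks a disappeared lesion.
    A ``(first_index, values)`` tuple declares a lesion appearing later.
    Default treatment is baseline SRS of all baseline lesions; default
    clinical observations are stable (KPS 90, BSS 1, no steroids).
    """
    first = {}
    tracks = {}
    for lid, traj in trajectories.items():
        if isinstance(traj, tuple):
            first[lid], tracks[lid] = traj
        else:
            first[lid], tracks[lid] = 0, traj
    n = max(f + len(v) for f, v in zip(first.values(), tracks.values()))
    if days is None:
        days = [91 * t for t in range(n)]
    lesions, measurements = [], []
    for lid, values in tracks.items():
        f = first[lid]
        lesions.append(
            Lesion(lesion_id=lid, first_seen_day=days[f], is_new_on_study=f > 0)
        )
        for offset, v in enumerate(values):
            t = f + offset
            if v is None:
                measurements.append(
                    LesionMeasurement(lid, t, 0.0, present=False)
                )
            else:
                measurements.append(LesionMeasurement(lid, t, float(v)))
    if treatments is None:
        treatments = [
            TreatmentEvent(
                "T1",
                Modality.SRS,
                0,
                frozenset(l.lesion_id for l in lesions if l.first_seen_day == days[0]),
            )
        ]
    if clinical is None:
        clinical = [
            ClinicalObservation(assessment_index=t, kps=90, bss=1) for t in range(n)
        ]
    return PatientCourse(
        patient_id=patient_id,
        assessment_days=list(days),
        lesions=lesions,
        treatments=treatments,
        measurements=measurements,
        clinical=clinical,
    )
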