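"""Programmatic course fixtures and a seeded stochastic course simulator.

The named fixtures encode the qualitative trajectories of a set of
hypothetical patient courses (two-lesion masking, mixed response,
varied DBF extent and rate, non-CNS KPS fluctuation, and sequential
SRS with growing target sets).  Concrete diameters are frozen fixture
constants; each fixture carries machine-checkable constraints stating
the relations it must satisfy, exercised by the test suite.

The simulator grows lesions exponentially, applies a multiplicative
per-modality treatment response with delayed regrowth, and draws new
lesions from a Poisson process thinned to assessment days.  Identical
parameters and seed yield an identical course.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Mapping, Optional, Sequence

import numpy as np

from .course_model import (
    ClinicalObservation,
    Lesion,
    LesionMeasurement,
    Modality,
    PatientCourse,
    QualitativeState,
    SteroidState,
    TreatmentEvent,
    months_to_days,
)

__all__ = [
    "SCENARIO_NAMES",
    "ScenarioSpec",
    "SimulationParams",
    "build_scenario",
    "scenario_spec",
    "simulate_course",
]

SCENARIO_NAMES = (
    "fig2_p1",
    "fig2_p2",
    "fig3_p1",
    "fig3_p2",
    "fig4_p1",
    "fig4_p2",
    "fig5_p1",
    "fig5_p2",
    "fig6_p1",
    "fig6_p2",
    "fig7",
    "fig8",
)


@dataclass(frozen=True)
class ScenarioSpec:
    name: str
    constraints: tuple[str, ...]


# -- fixture assembly helpers -------------------------------------------------


def _stable_clinical(n: int, kps: int = 90, bss: int = 1) -> list[ClinicalObservation]:
    return [
        ClinicalObservation(assessment_index=t, kps=kps, bss=bss, steroid_state=SteroidState.NONE)
        for t in range(n)
    ]


def _lesion_track(
    lesion_id: str,
    first_index: int,
    days: Sequence[int],
    lds: Sequence[Optional[float]],
) -> tuple[Lesion, list[LesionMeasurement]]:
    """Build a lesion plus measurements from ``first_index`` onward.

    ``lds`` holds one value per assessment starting at ``first_index``;
    ``None`` marks a disappeared (absent) lesion.
    """
    lesion = Lesion(
        lesion_id=lesion_id,
        first_seen_day=days[first_index],
        is_new_on_study=first_index > 0,
    )
    measurements = []
    for offset, ld in enumerate(lds):
        t = first_index + offset
        if ld is None:
            measurements.append(
                LesionMeasurement(
                    lesion_id=lesion_id,
                    assessment_index=t,
                    longest_diameter_mm=0.0,
                    present=False,
                    qualitative_state=QualitativeState.ABSENT,
                )
            )
        else:
            measurements.append(
                LesionMeasurement(
                    lesion_id=lesion_id,
                    assessment_index=t,
                    longest_diameter_mm=float(ld),
                )
            )
    return lesion, measurements


def _assemble(
    patient_id: str,
    days: list[int],
    tracks: list[tuple[str, int, Sequence[Optional[float]]]],
    treatments: list[TreatmentEvent],
    clinical: Optional[list[ClinicalObservation]] = None,
) -> PatientCourse:
    lesions, measurements = [], []
    for lid, first, lds in tracks:
        les, ms = _lesion_track(lid, first, days, lds)
        lesions.append(les)
        measurements.extend(ms)
    return PatientCourse(
        patient_id=patient_id,
        assessment_days=days,
        lesions=lesions,
        treatments=treatments,
        measurements=measurements,
        clinical=clinical if clinical is not None else _stable_clinical(len(days)),
    )


def _srs(treatment_id: str, day: int, *lesion_ids: str) -> TreatmentEvent:
    return TreatmentEvent(
        treatment_id=treatment_id,
        modality=Modality.SRS,
        start_day=day,
        targeted_lesion_ids=frozenset(lesion_ids),
    )


def _systemic(treatment_id: str, day: int) -> TreatmentEvent:
    return TreatmentEvent(
        treatment_id=treatment_id, modality=Modality.SYSTEMIC, start_day=day
    )


_QUARTERLY = [months_to_days(m) for m in (0, 3, 6, 9, 12)]


# -- fixture builders ---------------------------------------------------------


def _fig2_p1() -> PatientCourse:
    # both lesions shrink modestly; the sum never drops 30% below baseline
    return _assemble(
        "fig2_p1",
        list(_QUARTERLY),
        [
            ("L1", 0, [20, 18, 17, 16, 16]),
            ("L2", 0, [15, 14, 13, 13, 12]),
        ],
        [_srs("SRS1", 0, "L1", "L2")],
    )


def _fig2_p2() -> PatientCourse:
    # L1 ends >80% below baseline, L2 ends >=3x its nadir (+>=5 mm),
    # yet the sum stays above 70% of baseline throughout -> overall SD
    return _assemble(
        "fig2_p2",
        list(_QUARTERLY),
        [
            ("L1", 0, [20, 19, 16, 10, 3.8]),
            ("L2", 0, [10, 5, 11, 15, 17.5]),
        ],
        [_srs("SRS1", 0, "L1", "L2")],
    )


_FIG3_PD_TRACK = [20, 12, 8, 15, 26]  # shrinks, then >3x regrowth from nadir


def _fig3_p1() -> PatientCourse:
    return _assemble(
        "fig3_p1",
        list(_QUARTERLY),
        [("L1", 0, list(_FIG3_PD_TRACK))],
        [_srs("SRS1", 0, "L1")],
    )


def _fig3_p2() -> PatientCourse:
    return _assemble(
        "fig3_p2",
        list(_QUARTERLY),
        [
            ("L1", 0, list(_FIG3_PD_TRACK)),
            ("L2", 0, [15, 8, 4, None, None]),
            ("L3", 0, [12, 7, 5, 4, 3]),
            ("L4", 0, [11, 6, 4, 3, 3]),
            ("L5", 0, [10, 5, 3, 2, 2]),
        ],
        [_srs("SRS1", 0, "L1", "L2", "L3", "L4", "L5")],
    )


def _fig4_common(pid: str, late_tracks: list[tuple[str, int, Sequence[Optional[float]]]],
                 systemic_id: str) -> PatientCourse:
    tracks = [
        ("L0", 0, [15, 10, 9, 9, 9]),
        ("N1", 1, [8, 8, 8, 8]),
    ] + late_tracks
    return _assemble(
        pid,
        list(_QUARTERLY),
        tracks,
        [_srs("SRS1", 0, "L0"), _systemic(systemic_id, months_to_days(3))],
    )


def _fig4_p1() -> PatientCourse:
    # five simultaneous new lesions at month 9 under systemic therapy A
    late = [(f"G{i}", 3, [5 + i, 5 + i]) for i in range(1, 6)]
    return _fig4_common("fig4_p1", late, "SYS_A")


def _fig4_p2() -> PatientCourse:
    # one large new lesion at month 9 under systemic therapy B
    return _fig4_common("fig4_p2", [("G1", 3, [20, 20])], "SYS_B")


def _fig5_p1() -> PatientCourse:
    # original lesion resolves; one lesion present at systemic start, five new
    tracks = [("L0", 0, [14, None, None, None, None]), ("N1", 1, [9, 9, 9, 9])]
    tracks += [(f"G{i}", 3, [5 + i, 5 + i]) for i in range(1, 6)]
    return _assemble(
        "fig5_p1",
        list(_QUARTERLY),
        tracks,
        [_srs("SRS1", 0, "L0"), _systemic("SYS_A", months_to_days(3))],
    )


def _fig5_p2() -> PatientCourse:
    # five lesions present at systemic start, one new afterwards
    tracks = [("L0", 0, [14, None, None, None, None])]
    tracks += [(f"N{i}", 1, [12 - i, 12 - i, 12 - i, 12 - i]) for i in range(1, 6)]
    tracks += [("G1", 3, [22, 22])]
    return _assemble(
        "fig5_p2",
        list(_QUARTERLY),
        tracks,
        [_srs("SRS1", 0, "L0"), _systemic("SYS_B", months_to_days(3))],
    )


_FIG6_DAYS = [months_to_days(m) for m in (0, 4, 8, 12, 16)]


def _fig6_p1() -> PatientCourse:
    # one new lesion every 4 months over 12 months of follow-up
    return _assemble(
        "fig6_p1",
        list(_FIG6_DAYS),
        [
            ("L0", 0, [12, 12, 12, 12, 12]),
            ("N1", 1, [7, 7, 7, 7]),
            ("N2", 2, [8, 8, 8]),
            ("N3", 3, [6, 6]),
        ],
        [_systemic("SYS_A", 0)],
    )


def _fig6_p2() -> PatientCourse:
    # six simultaneous new lesions at month 12
    tracks = [("L0", 0, [12, 12, 12, 12, 12])]
    tracks += [(f"N{i}", 3, [6 + (i % 3), 6 + (i % 3)]) for i in range(1, 7)]
    return _assemble("fig6_p2", list(_FIG6_DAYS), tracks, [_systemic("SYS_B", 0)])


def _fig7() -> PatientCourse:
    # KPS dips for non-CNS reasons (attributed); BSS stable >100 weeks
    days = [week * 7 for week in range(0, 120, 12)]  # 0..108 weeks
    kps = [90, 90, 60, 90, 70, 90, 90, 60, 90, 90]
    clinical = [
        ClinicalObservation(
            assessment_index=t,
            kps=kps[t],
            bss=1,
            steroid_state=SteroidState.NONE,
            decline_attributed_to_non_cns=kps[t] < 90,
        )
        for t in range(len(days))
    ]
    return _assemble(
        "fig7",
        days,
        [("L0", 0, [12] * len(days))],
        [_srs("SRS1", 0, "L0")],
        clinical=clinical,
    )


_FIG8_DAYS = [months_to_days(m) for m in (0, 3, 6, 9, 12, 15, 18, 21)]


def _fig8() -> PatientCourse:
    baseline = {
        "B1": [22, 20, 18, 17, 16, 15, 15, 14],
        "B2": [18, 17, 15, 14, 13, 13, 12, 12],
        "B3": [15, 14, 13, 12, 11, 11, 10, 10],
        "B4": [14, 13, 12, 11, 11, 10, 10, 9],
        "B5": [12, 11, 10, 10, 9, 9, 8, 8],
        "B6": [11, 10, 9, 9, 8, 8, 8, 7],
        "B7": [10, 9, 9, 8, 8, 7, 7, 7],
    }
    tracks: list[tuple[str, int, Sequence[Optional[float]]]] = [
        (lid, 0, lds) for lid, lds in baseline.items()
    ]
    tracks += [
        ("N1", 1, [13, 11, 10, 9, 9, 8, 8]),
        ("N2", 1, [11, 10, 9, 8, 8, 7, 7]),
        ("N3", 1, [10, 9, 8, 8, 7, 7, 6]),
        ("N4", 5, [12, 10, 9]),
        ("N5", 5, [10, 9, 8]),
    ]
    treatments = [
        _srs("SRS1", 0, *baseline),
        _systemic("SYS", 0),
        _srs("SRS2", months_to_days(3), "N1", "N2", "N3"),
        _srs("SRS3", months_to_days(15), "N4", "N5"),
    ]
    return _assemble("fig8", list(_FIG8_DAYS), tracks, treatments)


_BUILDERS: dict[str, Callable[[], PatientCourse]] = {
    "fig2_p1": _fig2_p1,
    "fig2_p2": _fig2_p2,
    "fig3_p1": _fig3_p1,
    "fig3_p2": _fig3_p2,
    "fig4_p1": _fig4_p1,
    "fig4_p2": _fig4_p2,
    "fig5_p1": _fig5_p1,
    "fig5_p2": _fig5_p2,
    "fig6_p1": _fig6_p1,
    "fig6_p2": _fig6_p2,
    "fig7": _fig7,
    "fig8": _fig8,
}

_CONSTRAINTS: dict[str, tuple[str, ...]] = {
    "fig2_p1": (
        "two lesions, both shrinking",
        "sum of diameters stays above 70% of baseline at every assessment",
        "no lesion grows 20% and 5 mm above its nadir",
    ),
    "fig2_p2": (
        "one lesion ends more than 80% below its baseline diameter",
        "the other lesion ends at least 3x its nadir with at least 5 mm absolute gain",
        "sum of diameters stays above 70% of baseline at every assessment",
    ),
    "fig3_p1": (
        "single lesion shrinks then regrows to at least 3x its nadir with >=5 mm gain",
    ),
    "fig3_p2": (
        "five lesions: one progresses like the single-lesion course",
        "one lesion disappears (CR) and three shrink at least 30% (PR)",
    ),
    "fig4_p1": ("five new lesions appear simultaneously after the systemic therapy start",),
    "fig4_p2": ("one new lesion appears after the systemic therapy start",),
    "fig5_p1": ("exactly one lesion present at the systemic therapy start; five new afterwards",),
    "fig5_p2": ("exactly five lesions present at the systemic therapy start; one new afterwards",),
    "fig6_p1": ("one new lesion at each of months 4, 8, and 12, all later confirmed",),
    "fig6_p2": ("six new lesions at month 12, later confirmed",),
    "fig7": (
        "BSS constant across >100 weeks of follow-up",
        "every KPS decline is attributed to a non-CNS cause",
    ),
    "fig8": (
        "seven baseline lesions, all treated with SRS",
        "three new lesions at the first follow-up, treated with SRS",
        "two new lesions at month 15, treated with SRS",
    ),
}


def build_scenario(name: str) -> PatientCourse:
    """Return the fully concrete course for a named fixture."""
    try:
        builder = _BUILDERS[name]
    except KeyError:
        raise ValueError(
            f"unknown scenario {name!r}; valid names: {', '.join(SCENARIO_NAMES)}"
        ) from None
    return builder()


def scenario_spec(name: str) -> ScenarioSpec:
    if name not in _CONSTRAINTS:
        raise ValueError(f"unknown scenario {name!r}")
    return ScenarioSpec(name=name, constraints=_CONSTRAINTS[name])


# -- stochastic simulator -----------------------------------------------------


@dataclass(frozen=True)
class SimulationParams:
    """Parameters for the course simulator; the seed fully determines output."""

    n_baseline_lesions: int = 2
    baseline_diameter_log_mean: float = math.log(14.0)
    baseline_diameter_log_sd: float = 0.35
    growth_rate_mean: float = 0.05  # fractional LD growth per month
    growth_rate_sd: float = 0.02
    treatment_effect: Mapping[str, float] = field(
        default_factory=lambda: {"SRS": 0.80, "FSRT": 0.85, "WBRT": 0.90, "systemic": 0.95}
    )
    response_duration_months: float = 6.0  # shrink phase before regrowth
    treat_baseline_with: Optional[str] = "SRS"
    new_lesion_rate_per_year: float = 1.0
    new_lesion_diameter_log_mean: float = math.log(8.0)
    new_lesion_diameter_log_sd: float = 0.30
    measurement_noise_sd_mm: float = 0.0
    n_assessments: int = 5
    assessment_interval_days: int = 91
    seed: int = 0

    def validate(self) -> None:
        if self.n_baseline_lesions < 0:
            raise ValueError("n_baseline_lesions must be >= 0")
        if self.n_assessments < 2:
            raise ValueError("n_assessments must be >= 2")
        if self.assessment_interval_days < 1:
            raise ValueError("assessment_interval_days must be >= 1")
        for name in (
            "baseline_diameter_log_sd",
            "growth_rate_sd",
            "new_lesion_rate_per_year",
            "new_lesion_diameter_log_sd",
            "measurement_noise_sd_mm",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.treat_baseline_with is not None:
            Modality(self.treat_baseline_with)


#: lesion smaller than this measures as disappeared
_DETECTION_LIMIT_MM = 1.0


def simulate_course(params: SimulationParams) -> PatientCourse:
    """Simulate one patient course.

    Random draws are consumed in a fixed order — baseline diameters,
    baseline growth rates, then per assessment: arrival count, new
    diameters, new growth rates, measurement noise — so seeds are
    stable across refactors.
    """
    params.validate()
    rng = np.random.default_rng(params.seed)
    days = [t * params.assessment_interval_days for t in range(params.n_assessments)]
    interval_years = params.assessment_interval_days / 365.25

    base_d = rng.lognormal(
        params.baseline_diameter_log_mean,
        params.baseline_diameter_log_sd,
        params.n_baseline_lesions,
    )
    base_g = rng.normal(
        params.growth_rate_mean, params.growth_rate_sd, params.n_baseline_lesions
    )

    treated_factor = None
    if params.treat_baseline_with is not None:
        treated_factor = dict(params.treatment_effect).get(params.treat_baseline_with, 1.0)

    # (lesion_id, first_index, size_at_first, growth_rate, treated)
    lesions = [
        (f"B{i + 1}", 0, float(base_d[i]), float(base_g[i]), treated_factor is not None)
        for i in range(params.n_baseline_lesions)
    ]
    noise_draws: dict[tuple[str, int], float] = {}

    for t in range(1, params.n_assessments):
        arrivals = int(rng.poisson(params.new_lesion_rate_per_year * interval_years))
        new_d = rng.lognormal(
            params.new_lesion_diameter_log_mean,
            params.new_lesion_diameter_log_sd,
            arrivals,
        )
        new_g = rng.normal(params.growth_rate_mean, params.growth_rate_sd, arrivals)
        for j in range(arrivals):
            lesions.append((f"N{t}_{j + 1}", t, float(new_d[j]), float(new_g[j]), False))
        active = [les for les in lesions if les[1] <= t]
        noise = rng.normal(0.0, params.measurement_noise_sd_mm, len(active))
        for les, eps in zip(active, noise):
            noise_draws[(les[0], t)] = float(eps)

    def _true_size(size0: float, growth: float, treated: bool, months: float) -> float:
        if not treated or treated_factor is None:
            return size0 * (1.0 + growth) ** months
        shrink = min(months, params.response_duration_months)
        size = size0 * treated_factor**shrink
        regrow = months - shrink
        if regrow > 0:
            size *= (1.0 + max(growth, 0.0)) ** regrow
        return size

    lesion_objs, measurements = [], []
    for lid, first, size0, growth, treated in lesions:
        lesion_objs.append(
            Lesion(lesion_id=lid, first_seen_day=days[first], is_new_on_study=first > 0)
        )
        for t in range(first, params.n_assessments):
            months = (days[t] - days[first]) / 30.44
            size = _true_size(size0, growth, treated, months)
            size += noise_draws.get((lid, t), 0.0)
            size = max(size, 0.0)
            if size < _DETECTION_LIMIT_MM:
                measurements.append(
                    LesionMeasurement(
                        lesion_id=lid,
                        assessment_index=t,
                        longest_diameter_mm=0.0,
                        present=False,
                        qualitative_state=QualitativeState.ABSENT,
                    )
                )
            else:
                measurements.append(
                    LesionMeasurement(
                        lesion_id=lid,
                        assessment_index=t,
                        longest_diameter_mm=round(size, 2),
                    )
                )

    treatments = []
    if params.treat_baseline_with is not None and params.n_baseline_lesions:
        modality = Modality(params.treat_baseline_with)
        targeted = (
            frozenset(f"B{i + 1}" for i in range(params.n_baseline_lesions))
            if modality in {Modality.SRS, Modality.FSRT, Modality.SURGERY}
            else frozenset()
        )
        treatments.append(
            TreatmentEvent(
                treatment_id="T1", modality=modality, start_day=0, targeted_lesion_ids=targeted
            )
        )

    return PatientCourse(
        patient_id=f"sim-{params.seed}",
        assessment_days=days,
        lesions=lesion_objs,
        treatments=treatments,
        measurements=measurements,
        clinical=_stable_clinical(params.n_assessments),
    )
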