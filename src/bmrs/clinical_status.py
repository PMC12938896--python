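"""Clinical deterioration rules: KPS decline and the BSS symptom scale.

KPS deterioration follows three clauses evaluated against a fixed
reference (the course or window baseline): a drop from 90-100 to <=70,
a drop of >=20 points from a start of <=80, or any drop to <=50.
BSS worsening is a configurable increase (default one point) on the
0-5 brain-specific-symptoms scale.  Either signal can be suppressed by
attributing the decline to a non-CNS cause.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum
from typing import Optional, Sequence

from .course_model import VALID_KPS, ClinicalObservation
from .designation import AssessmentConfig, StatusMetric

__all__ = [
    "ClinicalState",
    "StatusEvaluation",
    "kps_deteriorated",
    "bss_worsened",
    "clinical_state",
    "evaluate_status",
]


class ClinicalState(str, Enum):
    STABLE_OR_IMPROVED = "stable_or_improved"
    WORSE = "worse"


@dataclass(frozen=True)
class StatusEvaluation:
    assessment_index: int
    kps_worse: Optional[bool]
    bss_worse: Optional[bool]
    combined_worse: bool
    attribution_excluded: bool


def _check_kps(value: int, label: str) -> None:
    if value not in VALID_KPS:
        raise ValueError(f"{label} KPS must be one of 0,10,...,100, got {value}")


def kps_deteriorated(baseline_kps: int, current_kps: int) -> bool:
    """KPS deterioration relative to the reference score."""
    _check_kps(baseline_kps, "baseline")
    _check_kps(current_kps, "current")
    if baseline_kps >= 90 and current_kps <= 70:
        return True
    if baseline_kps <= 80 and baseline_kps - current_kps >= 20:
        return True
    return current_kps <= 50


def bss_worsened(reference_bss: int, current_bss: int, cfg: AssessmentConfig) -> bool:
    """BSS worsening: increase of at least ``cfg.bss_worsen_delta`` points."""
    for label, value in (("reference", reference_bss), ("current", current_bss)):
        if not 0 <= value <= 5:
            raise ValueError(f"{label} BSS must be in 0..5, got {value}")
    return current_bss - reference_bss >= cfg.bss_worsen_delta


def evaluate_status(
    observations: Sequence[ClinicalObservation],
    t: int,
    cfg: AssessmentConfig,
) -> StatusEvaluation:
    """Evaluate deterioration at assessment ``t`` against the first observation.

    The reference is the observation at the course (or window) baseline,
    not the previous visit.  A metric is skipped when it is missing at
    either end or disabled by ``cfg.status_metric``.
    """
    by_index = {obs.assessment_index: obs for obs in observations}
    if not by_index:
        raise ValueError("no clinical observations supplied")
    reference = by_index[min(by_index)]
    current = by_index.get(t)
    if current is None:
        return StatusEvaluation(t, None, None, False, False)

    use_kps = cfg.status_metric in (StatusMetric.KPS, StatusMetric.BOTH)
    use_bss = cfg.status_metric in (StatusMetric.BSS, StatusMetric.BOTH)

    kps_worse: Optional[bool] = None
    if use_kps and reference.kps is not None and current.kps is not None:
        kps_worse = kps_deteriorated(reference.kps, current.kps)
    bss_worse: Optional[bool] = None
    if use_bss and reference.bss is not None and current.bss is not None:
        bss_worse = bss_worsened(reference.bss, current.bss, cfg)

    excluded = current.decline_attributed_to_non_cns
    combined = bool(kps_worse or bss_worse) and not excluded
    return StatusEvaluation(t, kps_worse, bss_worse, combined, excluded)


def clinical_state(
    observations: Sequence[ClinicalObservation],
    t: int,
    cfg: AssessmentConfig,
) -> ClinicalState:
    """Clinical-status component for the overall response at assessment ``t``."""
    if not observations:
        return ClinicalState.STABLE_OR_IMPROVED
    evaluation = evaluate_status(observations, t, cfg)
    return ClinicalState.WORSE if evaluation.combined_worse else ClinicalState.STABLE_OR_IMPROVED
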