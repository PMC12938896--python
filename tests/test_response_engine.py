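import numpy as np
import pytest

from bmrs import (
    AssessmentConfig,
    Category,
    ClinicalObservation,
    ClinicalState,
    CourseValidationError,
    LesionMeasurement,
    NontargetState,
    PdRule,
    SteroidState,
    assess_course,
    build_scenario,
    confirm_new_lesions,
    designate_a1,
    lesion_category,
    months_to_days,
    overall_response,
    target_category,
    windowed_assessment,
)

from _oracle import oracle_overall, random_course
from conftest import make_course


def track(values):
    return [(v if v is not None else 0.0, v is not None) for v in values]


class TestTargetCategory:
    def test_exact_30pct_decrease_is_pr(self, cfg):
        course = make_course({"L1": [20, 14], "L2": [20, 14]})
        timeline = designate_a1(course, cfg)
        assert target_category(timeline, course, 1, cfg) is Category.PR

    def test_pd_requires_both_clauses(self, cfg):
        # +20% on the sum AND one lesion +5 mm over its nadir
        course = make_course({"L1": [10, 15], "L2": [10, 9]})
        timeline = designate_a1(course, cfg)
        assert target_category(timeline, course, 1, cfg) is Category.PD

    def test_sum_increase_without_lesion_increase_is_sd(self, cfg):
        course = make_course({"L1": [10, 14], "L2": [10, 10]})
        timeline = designate_a1(course, cfg)
        assert target_category(timeline, course, 1, cfg) is Category.SD

    def test_all_absent_is_cr(self, cfg):
        course = make_course({"L1": [20, None], "L2": [15, None]})
        timeline = designate_a1(course, cfg)
        assert target_category(timeline, course, 1, cfg) is Category.CR

    def test_empty_target_set_is_ne(self, cfg):
        course = make_course({"L1": [8, 8]})
        timeline = designate_a1(course, cfg)
        assert target_category(timeline, course, 0, cfg) is Category.NE

    def test_absolute_rule(self):
        cfg = AssessmentConfig(pd_rule=PdRule.ABSOLUTE_2P5MM)
        course = make_course({"L1": [20, 23]})  # +3 mm: below 5, above 2.5
        timeline = designate_a1(course, cfg)
        assert target_category(timeline, course, 1, cfg) is Category.PD


class TestLesionCategory:
    def test_eighty_pct_shrink_is_pr(self, cfg):
        assert lesion_category(track([20, 4]), cfg)[-1] is Category.PR

    def test_threefold_regrowth_is_pd(self, cfg):
        cats = lesion_category(track([10, 6, 18]), cfg)
        assert cats == [Category.SD, Category.PR, Category.PD]

    def test_constant_is_sd(self, cfg):
        assert lesion_category(track([10, 10, 10]), cfg) == [Category.SD] * 3

    def test_disappearance_is_cr(self, cfg):
        assert lesion_category(track([10, None]), cfg)[-1] is Category.CR

    def test_empty_trajectory_raises(self, cfg):
        with pytest.raises(ValueError):
            lesion_category([], cfg)


class TestOverallResponse:
    def run(self, target, nontarget=NontargetState.NONE, new=False, confirmed=False,
            steroids=SteroidState.NONE, clinical=ClinicalState.STABLE_OR_IMPROVED,
            cfg=AssessmentConfig()):
        cat, _ = overall_response(target, nontarget, new, confirmed, steroids, clinical, cfg)
        return cat

    def test_cr_column(self):
        assert self.run(Category.CR) is Category.CR

    def test_cr_with_steroids_downgrades(self):
        assert self.run(Category.CR, steroids=SteroidState.STABLE) is Category.PR

    def test_pr_with_steroid_increase_is_ne(self):
        assert self.run(Category.PR, steroids=SteroidState.INCREASED) is Category.NE

    def test_sd_with_confirmed_new_lesion_is_pd(self):
        assert self.run(Category.SD, new=True, confirmed=True) is Category.PD

    def test_unconfirmed_new_lesion_blocks_sd(self):
        assert self.run(Category.SD, new=True, confirmed=False) is Category.NE

    def test_nontarget_progression_is_pd(self):
        assert (
            self.run(Category.PR, nontarget=NontargetState.UNEQUIVOCAL_PROGRESSION)
            is Category.PD
        )

    def test_clinical_worse_is_pd(self):
        assert self.run(Category.SD, clinical=ClinicalState.WORSE) is Category.PD

    def test_pd_reasons_recorded(self, cfg):
        cat, reasons = overall_response(
            Category.PD,
            NontargetState.UNEQUIVOCAL_PROGRESSION,
            True,
            True,
            SteroidState.INCREASED,
            ClinicalState.WORSE,
            cfg,
        )
        assert cat is Category.PD
        assert set(reasons) == {
            "PD:target_growth",
            "PD:nontarget_unequivocal_progression",
            "PD:new_lesions_confirmed",
            "PD:clinical_worse",
        }


class TestConfirmNewLesions:
    def test_persisting_lesion_confirmed_at_first_appearance(self, cfg):
        course = make_course({"L1": [20, 18, 17], "N1": (1, [8, 8])})
        assert confirm_new_lesions(course, cfg) == {1: frozenset({"N1"})}

    def test_terminal_appearance_pending(self, cfg):
        course = make_course({"L1": [20, 18, 17], "N1": (2, [8])})
        assert confirm_new_lesions(course, cfg) == {}

    def test_confirmation_disabled(self):
        cfg = AssessmentConfig(require_new_lesion_confirmation=False)
        course = make_course({"L1": [20, 18, 17], "N1": (2, [8])})
        assert confirm_new_lesions(course, cfg) == {2: frozenset({"N1"})}


class TestAssessCourse:
    def test_fig2_both_patients_sd_only_p2_flagged(self, cfg):
        r1 = assess_course(build_scenario("fig2_p1"), cfg)
        r2 = assess_course(build_scenario("fig2_p2"), cfg)
        for report in (r1, r2):
            assert all(
                tp.overall is Category.SD for tp in report.timepoints[1:]
            )
        assert not r1.discrepancy_flag
        assert r2.discrepancy_flag
        assert any(lr.final_category is Category.PD for lr in r2.lesions)

    def test_fig3_p2_mixed_response(self, cfg):
        report = assess_course(build_scenario("fig3_p2"), cfg)
        assert report.timepoints[-1].overall is Category.PD
        fractions = report.mixed_response_fractions
        assert fractions.get("CR", 0) + fractions.get("PR", 0) == pytest.approx(0.8)
        assert fractions["PD"] == pytest.approx(0.2)

    def test_single_lesion_overall_equals_lesion_response(self, cfg):
        course = make_course({"L1": [20, 12, 8, 15, 26]})
        report = assess_course(course, cfg)
        lesion = report.lesions[0]
        for tp in report.timepoints[1:]:
            assert tp.overall == lesion.categories[tp.assessment_index]

    def test_best_overall_and_ttp(self, cfg):
        report = assess_course(build_scenario("fig3_p1"), cfg)
        assert report.best_overall is Category.PR
        assert report.time_to_progression_days == months_to_days(9)

    def test_ttp_absent_without_pd(self, cfg):
        report = assess_course(build_scenario("fig2_p1"), cfg)
        assert report.time_to_progression_days is None

    def test_invalid_course_raises(self, cfg):
        course = make_course({"L1": [20, 18]})
        course.measurements.append(LesionMeasurement("L1", 9, 1.0))
        with pytest.raises(CourseValidationError):
            assess_course(course, cfg)

    def test_fractions_sum_to_one(self, cfg):
        report = assess_course(build_scenario("fig8"), cfg)
        assert sum(report.mixed_response_fractions.values()) == pytest.approx(1.0)

    def test_assessment_continues_after_pd(self, cfg):
        report = assess_course(build_scenario("fig6_p1"), cfg)
        pd_indices = [tp.assessment_index for tp in report.timepoints if tp.overall is Category.PD]
        assert pd_indices == [1, 2, 3]  # three separate DBF assessments


class TestWindowedAssessment:
    def test_identity_window(self, cfg):
        course = build_scenario("fig2_p1")
        full = assess_course(course, cfg)
        windowed = windowed_assessment(course, 0, cfg=cfg)
        assert windowed == full

    def test_fig5_patient1_window(self, cfg):
        report = windowed_assessment(build_scenario("fig5_p1"), months_to_days(3), cfg=cfg)
        initial = [lr.lesion_id for lr in report.lesions if lr.categories[0] is not Category.NE]
        assert initial == ["N1"]
        assert report.dbf_summary.total_new_lesions == 5

    def test_fig5_patient2_window(self, cfg):
        report = windowed_assessment(build_scenario("fig5_p2"), months_to_days(3), cfg=cfg)
        initial = [lr.lesion_id for lr in report.lesions if lr.categories[0] is not Category.NE]
        assert len(initial) == 5
        assert report.dbf_summary.total_new_lesions == 1

    def test_window_not_on_grid_raises(self, cfg):
        with pytest.raises(ValueError):
            windowed_assessment(build_scenario("fig5_p1"), 17, cfg=cfg)

    def test_window_too_short_raises(self, cfg):
        course = build_scenario("fig5_p1")
        with pytest.raises(ValueError):
            windowed_assessment(course, course.assessment_days[-1], cfg=cfg)


class TestEngineProperties:
    @pytest.mark.parametrize("seed", range(60))
    def test_oracle_equivalence(self, seed, cfg):
        course = random_course(np.random.default_rng(seed))
        report = assess_course(course, cfg)
        expected = oracle_overall(course)
        got = [tp.overall.value for tp in report.timepoints]
        assert got == expected

    @pytest.mark.parametrize("seed", range(15))
    @pytest.mark.parametrize("shrink", [0.9, 0.7, 0.5])
    def test_overall_monotone_under_uniform_shrinkage(self, seed, shrink):
        # fixed steroids/clinical/new-lesion inputs: shrinking every
        # post-baseline diameter never worsens the overall category
        rng = np.random.default_rng(1000 + seed)
        n = 5
        values = {
            f"L{i}": [round(float(rng.uniform(10, 40)), 1)]
            + [round(float(rng.uniform(5, 45)), 1) for _ in range(n - 1)]
            for i in range(1, 4)
        }
        cfg = AssessmentConfig()
        base = assess_course(make_course(values), cfg)
        shrunk_values = {
            lid: [vals[0]] + [round(v * shrink, 2) for v in vals[1:]]
            for lid, vals in values.items()
        }
        shrunk = assess_course(make_course(shrunk_values), cfg)
        rank = {Category.CR: 0, Category.PR: 1, Category.SD: 2, Category.PD: 3}
        for tp_base, tp_shrunk in zip(base.timepoints, shrunk.timepoints):
            assert rank[tp_shrunk.overall] <= rank[tp_base.overall]

    @pytest.mark.parametrize("seed", range(20))
    def test_absolute_rule_at_least_as_sensitive(self, seed):
        """A course that is target-PD under the default rule with a >=5 mm
        single-lesion increase is also PD under the 2.5 mm absolute rule."""
        course = random_course(np.random.default_rng(2000 + seed))
        rel = AssessmentConfig()
        absolute = AssessmentConfig(pd_rule=PdRule.ABSOLUTE_2P5MM)
        timeline = designate_a1(course, rel)
        for t in range(course.n_assessments):
            if target_category(timeline, course, t, rel) is Category.PD:
                assert target_category(timeline, course, t, absolute) is Category.PD

    def test_ttp_nondecreasing_in_abs_increase_threshold(self):
        course = make_course({"L1": [10, 13, 16, 20]})
        ttps = []
        for threshold in (2.0, 5.0, 8.0):
            cfg = AssessmentConfig(pd_abs_increase_mm=threshold)
            report = assess_course(course, cfg)
            ttps.append(
                report.time_to_progression_days
                if report.time_to_progression_days is not None
                else float("inf")
            )
        assert ttps == sorted(ttps)
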