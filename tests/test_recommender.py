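import numpy as np
import pytest
from sklearn.base import clone

from burnoutrec import (
    KnowledgeBase,
    ProgramRecommender,
    ValidRecord,
    audit_recommendation,
    cold_start_allocation,
    dominant_subdimension,
    recommend_stage1,
    recommend_stage2,
    update_knowledge_base,
)
from burnoutrec.recommender import DEFAULT_COLD_START_MAP

from conftest import make_profile, random_kb, random_profile


def record(schema, pid, program, effective, **profile_overrides):
    return ValidRecord(
        profile=make_profile(schema, pid=pid, **profile_overrides),
        program=program,
        effective_subdimension=effective,
        reduction=6.0,
    )


class TestDominantSubdimension:
    def test_unique_maximum(self):
        assert dominant_subdimension({"personal": 50, "work": 70, "client": 60}) == "work"

    def test_work_client_tie_resolves_to_work(self):
        assert dominant_subdimension({"personal": 10, "work": 80, "client": 80}) == "work"

    def test_all_equal_resolves_to_work(self):
        assert dominant_subdimension({"personal": 5, "work": 5, "client": 5}) == "work"

    def test_custom_priority(self):
        sub = dominant_subdimension(
            {"personal": 5, "work": 5, "client": 5}, priority=("client", "work", "personal")
        )
        assert sub == "client"


class TestColdStart:
    def test_default_map(self):
        assert cold_start_allocation("personal") == "mindfulness"
        assert cold_start_allocation("work") == "storytelling"
        assert cold_start_allocation("client") == "act"

    def test_mapped_program_excluded_falls_back(self):
        assert cold_start_allocation("personal", excluded={"mindfulness"}) == "laughter"

    def test_all_programs_excluded_raises(self):
        with pytest.raises(ValueError, match="all programs"):
            cold_start_allocation(
                "work", excluded={"mindfulness", "storytelling", "laughter", "act"}
            )


class TestStage1:
    def test_empty_kb_cold_start(self, schema):
        profile = make_profile(schema, burnout_personal=80, burnout_work=40, burnout_client=40)
        rec = recommend_stage1(KnowledgeBase(schema), profile)
        assert rec.cold_start
        assert rec.program == DEFAULT_COLD_START_MAP["personal"]

    def test_single_record_kb_returns_its_program(self, schema):
        kb = KnowledgeBase(schema)
        kb.append(record(schema, "K0", "laughter", "work"))
        rec = recommend_stage1(kb, make_profile(schema, burnout_work=90))
        assert rec.program == "laughter"
        assert rec.matched_record.insertion_index == 0

    def test_matching_filter_beats_proximity(self, schema):
        """A farther record with the matching effective subdimension wins
        over a nearer record treating a different subdimension."""
        kb = KnowledgeBase(schema)
        kb.append(record(schema, "far", "act", "work", age=60, turnover_intention=10))
        kb.append(record(schema, "near", "mindfulness", "personal"))
        profile = make_profile(schema, burnout_work=90, burnout_personal=10, burnout_client=10)
        rec = recommend_stage1(kb, profile)
        assert rec.program == "act"
        assert rec.candidate_pool == "matched"

    def test_fallback_to_all_when_no_match(self, schema):
        kb = KnowledgeBase(schema)
        kb.append(record(schema, "K0", "storytelling", "personal"))
        profile = make_profile(schema, burnout_client=95, burnout_personal=10, burnout_work=10)
        rec = recommend_stage1(kb, profile)
        assert rec.program == "storytelling"
        assert rec.candidate_pool == "all"

    def test_consistency_with_brute_force_scan(self, schema):
        from conftest import brute_force_dissimilarity

        rng = np.random.default_rng(11)
        kb = random_kb(schema, rng, 30)
        profile = random_profile(schema, rng, "new")
        rec = recommend_stage1(kb, profile)
        dominant = dominant_subdimension(profile.burnout_normalized(schema))
        pool = [r for r in kb if r.effective_subdimension == dominant] or list(kb)
        best = min(
            pool,
            key=lambda r: (
                brute_force_dissimilarity(schema, r.profile, profile),
                r.insertion_index,
            ),
        )
        assert rec.program == best.program

    def test_monotone_specialization(self, schema):
        """A strictly closer eligible record takes over the recommendation."""
        kb = KnowledgeBase(schema)
        kb.append(record(schema, "K0", "act", "work", age=55))
        profile = make_profile(schema, burnout_work=90, burnout_personal=10, burnout_client=10)
        assert recommend_stage1(kb, profile).program == "act"
        update_knowledge_base(
            kb, [record(schema, "K1", "laughter", "work", burnout_work=90,
                        burnout_personal=10, burnout_client=10)]
        )
        rec = recommend_stage1(kb, profile)
        assert rec.program == "laughter"
        assert rec.dissimilarity == pytest.approx(0.0)


class TestStage2:
    def test_program1_always_excluded(self, schema):
        rng = np.random.default_rng(21)
        for trial in range(20):
            kb = random_kb(schema, rng, 10, assessment_point="posttest1")
            profile = random_profile(schema, rng, "new", assessment_point="posttest1")
            program1 = ("mindfulness", "storytelling", "laughter", "act")[trial % 4]
            rec = recommend_stage2(kb, profile, program1)
            assert rec.program != program1

    def test_exclusion_forces_next_nearest(self, schema):
        kb = KnowledgeBase(schema)
        kb.append(record(schema, "K0", "laughter", "work"))
        kb.append(record(schema, "K1", "mindfulness", "work", age=50))
        profile = make_profile(
            schema, assessment_point="posttest1",
            burnout_work=90, burnout_personal=10, burnout_client=10,
        )
        rec = recommend_stage2(kb, profile, "laughter")
        assert rec.program == "mindfulness"

    def test_empty_eligible_set_cold_starts_over_remaining(self, schema):
        kb = KnowledgeBase(schema)
        kb.append(record(schema, "K0", "laughter", "work"))
        profile = make_profile(
            schema, assessment_point="posttest1",
            burnout_work=90, burnout_personal=10, burnout_client=10,
        )
        rec = recommend_stage2(kb, profile, "laughter")
        assert rec.cold_start
        assert rec.program != "laughter"
        assert rec.program == DEFAULT_COLD_START_MAP["work"]

    def test_unknown_program_rejected(self, schema):
        with pytest.raises(ValueError):
            recommend_stage2(KnowledgeBase(schema), make_profile(schema), "yoga")


class TestUpdate:
    def test_append_preserves_existing_order(self, schema):
        rng = np.random.default_rng(31)
        kb = random_kb(schema, rng, 10)
        before = list(kb.records)
        update_knowledge_base(kb, [record(schema, "new", "act", "client")])
        assert len(kb) == 11
        assert list(kb.records[:10]) == before

    def test_append_empty_is_identity(self, schema):
        rng = np.random.default_rng(32)
        kb = random_kb(schema, rng, 5)
        before = list(kb.records)
        update_knowledge_base(kb, [])
        assert list(kb.records) == before

    def test_duplicate_participant_stage_rejected(self, schema):
        kb = KnowledgeBase(schema)
        kb.append(record(schema, "P9", "act", "client"))
        with pytest.raises(ValueError, match="duplicate"):
            kb.append(record(schema, "P9", "laughter", "work"))


class TestAudit:
    def test_report_rows_and_consistency(self, schema):
        rng = np.random.default_rng(41)
        kb = random_kb(schema, rng, 3)
        profile = random_profile(schema, rng, "new")
        report = audit_recommendation(kb, profile, stage=1)
        assert len(report.rows) >= 1
        top_record, top_total, top_breakdown = report.rows[0]
        assert top_record.program == report.recommendation.program
        assert top_total == pytest.approx(top_breakdown.total)
        totals = [t for _, t, _ in report.rows]
        assert totals == sorted(totals)
        assert all(0 <= t <= len(schema.stage1_vars) for t in totals)


class TestEstimatorSurface:
    def test_get_params_clone_and_predict(self, schema):
        est = ProgramRecommender(schema=schema, tie_priority=("client", "work", "personal"))
        cloned = clone(est)
        assert cloned.get_params()["tie_priority"] == ("client", "work", "personal")
        rng = np.random.default_rng(51)
        est.fit(random_kb(schema, rng, 8))
        programs = est.predict([random_profile(schema, rng, f"p{i}") for i in range(4)])
        assert len(programs) == 4
        assert all(p in ("mindfulness", "storytelling", "laughter", "act") for p in programs)

    def test_partial_fit_appends(self, schema):
        est = ProgramRecommender(schema=schema).fit([])
        est.partial_fit([record(schema, "P1", "act", "client")])
        est.partial_fit([record(schema, "P2", "laughter", "work")])
        assert len(est.knowledge_base_) == 2

    def test_unfitted_predict_raises(self, schema):
        with pytest.raises(RuntimeError, match="not fitted"):
            ProgramRecommender(schema=schema).recommend(make_profile(schema))

    def test_determinism(self, schema):
        rng = np.random.default_rng(61)
        kb = random_kb(schema, rng, 12)
        profile = random_profile(schema, rng, "new")
        first = recommend_stage1(kb, profile)
        second = recommend_stage1(kb, profile)
        assert first == second
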