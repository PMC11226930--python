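import logging

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from burnoutrec import (
    KnowledgeBase,
    ValidRecord,
    categorical_element_dissimilarity,
    numerical_element_dissimilarity,
    profile_dissimilarity,
    rank_records,
    load_schema,
)

from conftest import brute_force_dissimilarity, make_profile, random_kb, random_profile


class TestElementRules:
    def test_categorical_mismatch_is_one(self):
        # marital-status codes of an existing user (1) vs a new user (3)
        assert categorical_element_dissimilarity(1, 3) == 1.0

    @pytest.mark.parametrize("code", [1, "ICU", (2, 3)])
    def test_categorical_match_is_zero(self, code):
        assert categorical_element_dissimilarity(code, code) == 0.0

    def test_categorical_string_codes(self):
        assert categorical_element_dissimilarity("ICU", "general ward") == 1.0

    def test_code_outside_allowed_set_rejected(self):
        with pytest.raises(ValueError, match="allowed set"):
            categorical_element_dissimilarity(1, 9, codes=(1, 2, 3))

    @pytest.mark.parametrize(
        "a,b,R,expected",
        [
            (45, 45, 38, 0.0),  # equal ages, any positive range
            (5, 3, 4, 0.50),  # hospital-size codes on 1..5
            (5, 4, 4, 0.25),
            (3, 1, 5, 0.40),  # experience bands on 1..6
            (3, 2, 5, 0.20),
        ],
    )
    def test_range_scaled_difference(self, a, b, R, expected):
        assert numerical_element_dissimilarity(a, b, R) == pytest.approx(expected)

    def test_printed_age_contributions_reproduced(self):
        # ages 30 and 25 vs a new user aged 45, on the 22-60 range (R=38)
        assert round(numerical_element_dissimilarity(30, 45, 38), 2) == 0.39
        assert round(numerical_element_dissimilarity(25, 45, 38), 2) == 0.53

    def test_out_of_range_difference_clipped_with_warning(self, caplog):
        with caplog.at_level(logging.WARNING, logger="burnoutrec.similarity"):
            assert numerical_element_dissimilarity(0, 10, 4) == 1.0
        assert "clipping" in caplog.text

    def test_degenerate_variable_equality_rule(self):
        assert numerical_element_dissimilarity(3, 3, 0, degenerate=True) == 0.0
        assert numerical_element_dissimilarity(3, 4, 0, degenerate=True) == 1.0

    def test_zero_range_without_flag_rejected(self):
        with pytest.raises(ValueError):
            numerical_element_dissimilarity(1, 2, 0)


def _paired_profiles(schema, seed):
    rng = np.random.default_rng(seed)
    return random_profile(schema, rng, "a"), random_profile(schema, rng, "b")


class TestProfileDissimilarity:
    def test_identical_profiles_total_zero(self, schema):
        p = make_profile(schema)
        assert profile_dissimilarity(p, p, schema).total == 0.0

    @settings(max_examples=60, deadline=None, derandomize=True)
    @given(seed=st.integers(0, 2**31 - 1))
    def test_symmetry(self, schema, seed):
        p, q = _paired_profiles(schema, seed)
        assert profile_dissimilarity(p, q, schema).total == pytest.approx(
            profile_dissimilarity(q, p, schema).total
        )

    @settings(max_examples=60, deadline=None, derandomize=True)
    @given(seed=st.integers(0, 2**31 - 1))
    def test_bounds_and_breakdown_sum(self, schema, seed):
        p, q = _paired_profiles(schema, seed)
        b = profile_dissimilarity(p, q, schema)
        assert all(0.0 <= c <= 1.0 for c in b.per_element.values())
        assert 0.0 <= b.total <= schema.max_dissimilarity
        assert b.total == pytest.approx(sum(b.per_element.values()))

    @settings(max_examples=60, deadline=None, derandomize=True)
    @given(seed=st.integers(0, 2**31 - 1))
    def test_matches_brute_force_oracle(self, schema, seed):
        p, q = _paired_profiles(schema, seed)
        assert profile_dissimilarity(p, q, schema).total == pytest.approx(
            brute_force_dissimilarity(schema, p, q)
        )

    @settings(max_examples=40, deadline=None, derandomize=True)
    @given(seed=st.integers(0, 2**31 - 1), n_cat=st.integers(0, 3), n_num=st.integers(0, 3))
    def test_small_random_schemas_match_oracle(self, seed, n_cat, n_num):
        if n_cat + n_num == 0:
            return
        rng = np.random.default_rng(seed)
        variables = [
            {"name": f"c{i}", "kind": "categorical", "codes": list(range(1 + rng.integers(1, 5)))}
            for i in range(n_cat)
        ] + [
            {
                "name": f"n{i}",
                "kind": "numerical",
                "min": float(lo := rng.uniform(-5, 5)),
                "max": float(lo + rng.uniform(0.5, 10)),
            }
            for i in range(n_num)
        ]
        s = load_schema({"variables": variables})
        p, q = random_profile(s, rng, "a"), random_profile(s, rng, "b")
        assert profile_dissimilarity(p, q, s).total == pytest.approx(
            brute_force_dissimilarity(s, p, q)
        )

    def test_missing_variable_raises(self, schema):
        p = make_profile(schema)
        q = p.to_dict()
        del q["numerical_values"]["age"]
        from burnoutrec import ParticipantProfile

        with pytest.raises(ValueError, match="age"):
            profile_dissimilarity(p, ParticipantProfile.from_dict(q), schema)

    def test_stage_subset_restricts_elements(self, schema):
        p, q = _paired_profiles(schema, 7)
        b = profile_dissimilarity(p, q, schema, schema.stage2_vars)
        assert set(b.per_element) == set(schema.stage2_vars)


class TestRankRecords:
    def test_ascending_order_and_vectorized_totals(self, schema):
        rng = np.random.default_rng(3)
        kb = random_kb(schema, rng, 25)
        new = random_profile(schema, rng, "new")
        ranked = rank_records(kb, new)
        totals = [t for _, t in ranked]
        assert totals == sorted(totals)
        assert len(ranked) == 25
        for rec, total in ranked[:5]:
            assert total == pytest.approx(
                brute_force_dissimilarity(schema, rec.profile, new)
            )

    def test_single_candidate_first(self, schema):
        rng = np.random.default_rng(4)
        kb = random_kb(schema, rng, 1)
        ranked = rank_records(kb, random_profile(schema, rng, "new"))
        assert ranked[0][0] is kb[0]

    def test_equal_totals_break_by_insertion_index(self, schema):
        kb = KnowledgeBase(schema)
        p = make_profile(schema, pid="same1")
        for i, pid in enumerate(["same1", "same2"]):
            kb.append(
                ValidRecord(
                    profile=make_profile(schema, pid=pid),
                    program="act" if i else "laughter",
                    effective_subdimension="work",
                    reduction=6.0,
                )
            )
        ranked = rank_records(kb, make_profile(schema, pid="new"))
        assert [r.insertion_index for r, _ in ranked] == [0, 1]
        assert ranked[0][1] == pytest.approx(ranked[1][1])

    def test_empty_candidate_set_signals_cold_start(self, schema):
        kb = KnowledgeBase(schema)
        assert rank_records(kb, make_profile(schema)) == []
        rng = np.random.default_rng(5)
        kb = random_kb(schema, rng, 5)
        assert rank_records(kb, make_profile(schema), candidate_filter=lambda r: False) == []
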