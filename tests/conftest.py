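import numpy as np
import pytest

from burnoutrec import (
    KnowledgeBase,
    ParticipantProfile,
    PROGRAMS,
    SUBDIMENSIONS,
    ValidRecord,
    default_schema,
)


@pytest.fixture(scope="session")
def schema():
    return default_schema()


def make_profile(schema, pid="P1", assessment_point="pretest", **overrides):
    """Profile with every variable at a default (first code / midpoint)."""
    cat = {v.name: v.codes[0] for v in schema.categorical}
    num = {v.name: (v.vmin + v.vmax) / 2.0 for v in schema.numerical}
    for key, val in overrides.items():
        if key in cat:
            cat[key] = val
        elif key in num:
            num[key] = float(val)
        else:
            raise KeyError(key)
    return ParticipantProfile(
        participant_id=pid,
        categorical_values=cat,
        numerical_values=num,
        assessment_point=assessment_point,
    )


def random_profile(schema, rng, pid="R", assessment_point="pretest"):
    cat = {v.name: v.codes[rng.integers(len(v.codes))] for v in schema.categorical}
    num = {
        v.name: float(rng.uniform(v.vmin, v.vmax)) if not v.degenerate else v.vmin
        for v in schema.numerical
    }
    return ParticipantProfile(
        participant_id=pid,
        categorical_values=cat,
        numerical_values=num,
        assessment_point=assessment_point,
    )


def random_kb(schema, rng, size, assessment_point="pretest"):
    """Knowledge base of random valid records (reductions all >= 5)."""
    kb = KnowledgeBase(schema)
    for i in range(size):
        kb.append(
            ValidRecord(
                profile=random_profile(schema, rng, pid=f"K{i}", assessment_point=assessment_point),
                program=PROGRAMS[rng.integers(4)],
                effective_subdimension=SUBDIMENSIONS[rng.integers(3)],
                reduction=float(rng.uniform(5.0, 20.0)),
            )
        )
    return kb


def brute_force_dissimilarity(schema, p, q, vars=None):
    """Independent re-implementation: per-element rules summed directly."""
    total = 0.0
    names = vars if vars is not None else schema.variable_names
    for name in names:
        if schema.is_categorical(name):
            total += 0.0 if p.categorical_values[name] == q.categorical_values[name] else 1.0
        else:
            v = schema.numerical_var(name)
            a, b = p.numerical_values[name], q.numerical_values[name]
            if v.range == 0:
                total += 0.0 if a == b else 1.0
            else:
                total += min(abs(a - b) / v.range, 1.0)
    return total
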