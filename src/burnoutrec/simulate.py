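"""Synthetic nurse-cohort generator and closed-loop trial replay.

The generator emulates the study conditions of a single-arm, two-stage
tailored intervention trial: it samples pretest profiles whose marginals
match the published cohort description (mean age 32.81, 97.7% female,
62.3% in 500+-bed hospitals, ...), and simulates per-program burnout
responses whose expected total reductions match the published
program-level effects (laughter 5.4, storytelling 4.6, ACT 7.9,
mindfulness 2.6 points on the 0–100 total scale).

Per-subdimension response means are expressed on the normalized 0–100
subdimension scale; weighted by the subdomain maxima (31.5, 37, 31.5
out of 100) they sum to the total-scale effects above, which keeps the
response model consistent with the validity screen's normalized 5-point
threshold.

``run_closed_loop_trial`` replays the sequential deployment loop —
pretest, stage-1 recommendation, simulated outcome, validity screen,
knowledge-base update, stage-2 recommendation, outcome, update — under
interchangeable allocation policies (the similarity engine, random,
fixed-program, or an oracle that knows the simulated subgroup truth).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any, Mapping

import numpy as np
import pandas as pd

from .recommender import (
    DEFAULT_FALLBACK_ORDER,
    ProgramRecommender,
    dominant_subdimension,
)
from .schema import (
    PROGRAMS,
    SUBDIMENSIONS,
    BurnoutScores,
    FeatureSchema,
    KnowledgeBase,
    ParticipantProfile,
    ProgramOutcome,
    ValidRecord,
    default_schema,
)
from .validity import classify_validity, subdimension_reductions

__all__ = [
    "CohortSpec",
    "TrialResult",
    "default_cohort_spec",
    "structured_cohort_spec",
    "homogeneous_cohort_spec",
    "sample_cohort",
    "simulate_response",
    "run_closed_loop_trial",
    "subgroup_best_program",
    "subgroup_match_rate",
]

#: Months-of-experience cut points mapping to band codes 1..6.
CLINICAL_EXPERIENCE_BANDS = (12.0, 36.0, 72.0, 120.0, 240.0)

#: Cohort marginals: category proportions or (mean, sd) of the published
#: participant table.
DEFAULT_MARGINALS: dict[str, dict[str, Any]] = {
    "sex": {"probs": {1: 0.977, 2: 0.023}},
    "marital_status": {"probs": {1: 0.593, 2: 0.393, 3: 0.014}},
    "position": {"probs": {1: 0.870, 2: 0.117, 3: 0.013}},
    "department": {"probs": {1: 0.573, 2: 0.053, 3: 0.100, 4: 0.210, 5: 0.064}},
    "shift_type": {"probs": {1: 0.600, 2: 0.060, 3: 0.337, 4: 0.003}},
    "age": {"mean": 32.81, "sd": 5.754},
    "hospital_size": {"probs": {1: 0.023, 2: 0.083, 3: 0.210, 4: 0.060, 5: 0.623}},
    "clinical_experience_months": {"mean": 95.83, "sd": 69.66},
    "overtime": {
        "probs": {1: 0.137, 2: 0.260, 3: 0.257, 4: 0.167, 5: 0.057, 6: 0.123}
    },
    "turnover_intention": {"mean": 4.88, "sd": 2.53},
    "job_stress": {"mean": 88.39, "sd": 12.65},
    "stress_response": {"mean": 42.00, "sd": 17.95},
    "coping_total": {"mean": 70.25, "sd": 9.66},
    "burnout_personal_raw": {"mean": 20.40, "sd": 6.39},
    "burnout_work_raw": {"mean": 22.22, "sd": 6.39},
    "burnout_client_raw": {"mean": 19.72, "sd": 6.63},
}

#: Per-program mean (sd) burnout reduction on the normalized 0–100
#: subdimension scale.  Weighted by subdomain maxima the means reproduce
#: the published total-scale effects.
DEFAULT_RESPONSE_MODEL: dict[str, dict[str, tuple[float, float]]] = {
    "laughter": {"personal": (6.9, 10.4), "work": (4.3, 7.2), "client": (5.2, 8.7)},
    "storytelling": {"personal": (4.2, 8.0), "work": (5.6, 10.5), "client": (3.8, 7.4)},
    "act": {"personal": (4.9, 7.9), "work": (6.4, 10.5), "client": (12.7, 18.2)},
    "mindfulness": {"personal": (3.0, 4.9), "work": (2.2, 4.0), "client": (2.7, 4.8)},
}


@dataclass
class CohortSpec:
    """Study conditions for one simulated cohort.

    ``heterogeneity``, when set, declares subgroup structure::

        {"variable": ("department", "shift_type"),
         "groups": {(1, 1): {"work": {"laughter": 14.0}, ...}, ...},
         "covariate_shifts": {"job_stress": {(1, 1): -14.0, ...}}}

    i.e. per stratum (one categorical variable or a tuple of them) and
    per burnout subdimension, bonus reductions in normalized points for
    the programs that genuinely act on that subdimension there — applied
    to whoever receives the program — plus optional per-stratum mean
    shifts of numerical covariates (strata with distinct profiles are
    what the nearest-neighbor search can actually exploit).
    Satisfaction is base + match bonus when the assigned program is the
    stratum's best for the current dominant subdimension, drawn with
    the given SD and discretized to 1..5.
    """

    n: int = 300
    marginals: dict[str, dict[str, Any]] = field(
        default_factory=lambda: {k: dict(v) for k, v in DEFAULT_MARGINALS.items()}
    )
    response_model: dict[str, dict[str, tuple[float, float]]] = field(
        default_factory=lambda: {
            p: dict(v) for p, v in DEFAULT_RESPONSE_MODEL.items()
        }
    )
    heterogeneity: dict[str, Any] | None = None
    satisfaction_base: float = 4.6
    satisfaction_match_bonus: float = 0.3
    satisfaction_sd: float = 0.6
    dropout_rate: float = 0.0
    schema: FeatureSchema = field(default_factory=default_schema)

    def __post_init__(self) -> None:
        if self.n < 0:
            raise ValueError("n must be >= 0")
        if not (0.0 <= self.dropout_rate < 1.0):
            raise ValueError("dropout_rate must be in [0, 1)")
        if self.satisfaction_sd < 0:
            raise ValueError("satisfaction_sd must be >= 0")
        for name, marg in self.marginals.items():
            if "probs" in marg:
                total = sum(marg["probs"].values())
                if not np.isclose(total, 1.0, atol=0.02):
                    raise ValueError(
                        f"{name!r}: category proportions sum to {total}, not 1"
                    )
            elif "mean" in marg:
                if marg.get("sd", 0.0) < 0:
                    raise ValueError(f"{name!r}: sd must be >= 0")
            else:
                raise ValueError(f"{name!r}: marginal needs 'probs' or 'mean'/'sd'")
        for prog, effects in self.response_model.items():
            if prog not in PROGRAMS:
                raise ValueError(f"unknown program {prog!r} in response model")
            for sub, (_, sd) in effects.items():
                if sub not in SUBDIMENSIONS:
                    raise ValueError(f"unknown subdimension {sub!r}")
                if sd < 0:
                    raise ValueError(f"{prog}/{sub}: sd must be >= 0")


def default_cohort_spec(n: int = 300) -> CohortSpec:
    """The calibrated study conditions: published marginals and effects."""
    return CohortSpec(n=n)


def structured_cohort_spec(n: int = 300) -> CohortSpec:
    """Strong-subgroup conditions for positive-control experiments.

    Base program effects are weak and identical (mean 0.5, SD 2.5
    normalized points per subdimension), so the validity screen admits
    almost exclusively genuinely effective program stages.  Subgroups
    are the 20 department-by-shift strata, sampled uniformly so no
    stratum dominates the knowledge base; each stratum assigns three of
    the four programs to distinct burnout subdimensions (+14 normalized
    points on the designated subdimension, for whoever receives the
    program), leaving one inert program per stratum.  Strata carry
    distinct work-stress signatures (shifted job stress, stress
    response, turnover intention, overtime, age, experience) so profile
    similarity can genuinely identify them; pretest burnout
    subdimensions share a common mean so dominance is uniform across
    subdimensions.
    """
    weak = {s: (0.5, 2.5) for s in SUBDIMENSIONS}
    groups: dict[tuple, dict[str, dict[str, float]]] = {}
    shifts: dict[str, dict[tuple, float]] = {
        "job_stress": {},
        "turnover_intention": {},
        "age": {},
        "stress_response": {},
        "overtime": {},
        "clinical_experience": {},
    }
    for d in range(1, 6):
        for sh in range(1, 5):
            i = (2 * d + 3 * sh) % 4
            groups[(d, sh)] = {
                sub: {PROGRAMS[(i + k) % 4]: 14.0}
                for k, sub in enumerate(SUBDIMENSIONS)
            }
            shifts["job_stress"][(d, sh)] = (d - 3) * 17.5
            shifts["turnover_intention"][(d, sh)] = (d - 3) * 3.75
            shifts["age"][(d, sh)] = (d - 3) * 10.0
            shifts["stress_response"][(d, sh)] = (sh - 2.5) * 15.0
            shifts["overtime"][(d, sh)] = (sh - 2.5) * 1.3
            shifts["clinical_experience"][(d, sh)] = (sh - 2.5) * 1.3
    marginals = {k: dict(v) for k, v in DEFAULT_MARGINALS.items()}
    marginals["department"] = {"probs": {d: 0.2 for d in range(1, 6)}}
    marginals["shift_type"] = {"probs": {s: 0.25 for s in range(1, 5)}}
    # equal normalized pretest means (62.5) and SDs (8) per subdimension
    marginals["burnout_personal_raw"] = {"mean": 62.5 * 0.315, "sd": 8.0 * 0.315}
    marginals["burnout_work_raw"] = {"mean": 62.5 * 0.37, "sd": 8.0 * 0.37}
    marginals["burnout_client_raw"] = {"mean": 62.5 * 0.315, "sd": 8.0 * 0.315}
    return CohortSpec(
        n=n,
        marginals=marginals,
        response_model={p: dict(weak) for p in PROGRAMS},
        heterogeneity={
            "variable": ("department", "shift_type"),
            "groups": groups,
            "covariate_shifts": shifts,
        },
    )


def homogeneous_cohort_spec(n: int = 300) -> CohortSpec:
    """Negative-control conditions: every program has the same response."""
    same = {s: (3.0, 6.0) for s in SUBDIMENSIONS}
    return CohortSpec(n=n, response_model={p: dict(same) for p in PROGRAMS})


# -- cohort sampling -----------------------------------------------------


def _sample_categorical(marg: Mapping[str, Any], rng: np.random.Generator):
    codes = list(marg["probs"].keys())
    p = np.array(list(marg["probs"].values()), dtype=float)
    p = p / p.sum()
    return codes[rng.choice(len(codes), p=p)]


def _sample_normal_clipped(
    marg: Mapping[str, Any], lo: float, hi: float, rng: np.random.Generator
) -> float:
    return float(np.clip(rng.normal(marg["mean"], marg["sd"]), lo, hi))


def _experience_band(months: float) -> int:
    for code, cut in enumerate(CLINICAL_EXPERIENCE_BANDS, start=1):
        if months < cut:
            return code
    return len(CLINICAL_EXPERIENCE_BANDS) + 1


def sample_participant(
    spec: CohortSpec, participant_id: str, rng: np.random.Generator
) -> ParticipantProfile:
    """Draw one pretest profile from the cohort marginals."""
    m = spec.marginals
    schema = spec.schema

    def bounds(name: str) -> tuple[float, float]:
        v = schema.numerical_var(name)
        return v.vmin, v.vmax

    cat = {
        "sex": _sample_categorical(m["sex"], rng),
        "marital_status": _sample_categorical(m["marital_status"], rng),
        "position": _sample_categorical(m["position"], rng),
        "department": _sample_categorical(m["department"], rng),
        "shift_type": _sample_categorical(m["shift_type"], rng),
    }
    exp = m["clinical_experience_months"]
    months = max(1.0, rng.normal(exp["mean"], exp["sd"]))
    raw_burnout = BurnoutScores(
        personal=_sample_normal_clipped(m["burnout_personal_raw"], 0.0, 31.5, rng),
        work_related=_sample_normal_clipped(m["burnout_work_raw"], 0.0, 37.0, rng),
        client_related=_sample_normal_clipped(m["burnout_client_raw"], 0.0, 31.5, rng),
    )
    norm = raw_burnout.normalized
    # coping subscales scatter around a third of the sampled total
    total_target = rng.normal(m["coping_total"]["mean"], m["coping_total"]["sd"])
    subscales = np.clip(total_target / 3.0 + rng.normal(0.0, 2.0, size=3), 11.0, 33.0)
    num = {
        "age": _sample_normal_clipped(m["age"], *bounds("age"), rng),
        "hospital_size": float(_sample_categorical(m["hospital_size"], rng)),
        "clinical_experience": float(_experience_band(months)),
        "overtime": float(_sample_categorical(m["overtime"], rng)),
        "turnover_intention": _sample_normal_clipped(
            m["turnover_intention"], *bounds("turnover_intention"), rng
        ),
        "job_stress": _sample_normal_clipped(m["job_stress"], *bounds("job_stress"), rng),
        "stress_response": _sample_normal_clipped(
            m["stress_response"], *bounds("stress_response"), rng
        ),
        "coping_problem_solving": float(subscales[0]),
        "coping_social_support": float(subscales[1]),
        "coping_avoidance": float(subscales[2]),
        "coping_total": float(subscales.sum()),
        "burnout_personal": norm["personal"],
        "burnout_work": norm["work"],
        "burnout_client": norm["client"],
        "reserved_1": 0.0,
        "reserved_2": 0.0,
        "reserved_3": 0.0,
    }
    het = spec.heterogeneity
    if het is not None and het.get("covariate_shifts"):
        hvar = het["variable"]
        if isinstance(hvar, (list, tuple)):
            stratum = tuple(cat.get(v, num.get(v)) for v in hvar)
        else:
            stratum = cat.get(hvar, num.get(hvar))
        for var, shifts in het["covariate_shifts"].items():
            v = schema.numerical_var(var)
            num[var] = float(
                np.clip(num[var] + shifts.get(stratum, 0.0), v.vmin, v.vmax)
            )
    profile = ParticipantProfile(
        participant_id=participant_id,
        categorical_values=cat,
        numerical_values=num,
        assessment_point="pretest",
    )
    schema.validate_profile(profile)
    return profile


def sample_cohort(
    spec: CohortSpec, rng: np.random.Generator | int | None = None
) -> list[ParticipantProfile]:
    """Sample ``spec.n`` pretest profiles; reproducible given a seed."""
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    return [sample_participant(spec, f"P{i + 1:04d}", rng) for i in range(spec.n)]


# -- response simulation -------------------------------------------------


def _value(spec: CohortSpec, profile: ParticipantProfile, var: str):
    if spec.schema.is_categorical(var):
        return profile.categorical_values[var]
    return profile.numerical_values[var]


def _stratum(spec: CohortSpec, profile: ParticipantProfile):
    het = spec.heterogeneity
    if het is None or "variable" not in het:
        return None
    var = het["variable"]
    if isinstance(var, (list, tuple)):
        return tuple(_value(spec, profile, v) for v in var)
    return _value(spec, profile, var)


def _bonus_by_subdimension(
    spec: CohortSpec, profile: ParticipantProfile, program: str, dominant: str
) -> dict[str, float]:
    """Extra normalized-points reduction per subdimension for one program.

    The ``groups`` table gives, per stratum, a subdimension ->
    {program: bonus} mapping: the program acts on its designated
    subdimension whoever receives it.
    """
    het = spec.heterogeneity
    if het is None:
        return {}
    table = het["groups"].get(_stratum(spec, profile), {})
    return {
        sub: progs[program] for sub, progs in table.items() if program in progs
    }


def _subgroup_bonuses(
    spec: CohortSpec, profile: ParticipantProfile, dominant: str
) -> Mapping[str, float]:
    """Per-program bonus on the given dominant subdimension (for ranking programs)."""
    het = spec.heterogeneity
    if het is None:
        return {}
    return {
        prog: _bonus_by_subdimension(spec, profile, prog, dominant).get(dominant, 0.0)
        for prog in PROGRAMS
    }


def subgroup_best_program(spec: CohortSpec, profile: ParticipantProfile) -> str | None:
    """Best program for this stratum given the profile's current dominant subdimension."""
    dominant = dominant_subdimension(profile.burnout_normalized(spec.schema))
    bonuses = _subgroup_bonuses(spec, profile, dominant)
    if not bonuses:
        return None
    return max(bonuses, key=lambda p: bonuses[p])


def simulate_response(
    profile: ParticipantProfile,
    program: str,
    spec: CohortSpec,
    rng: np.random.Generator | int | None = None,
) -> ProgramOutcome:
    """Simulate one program stage: post-scores and satisfaction.

    Each subdimension's normalized score drops by a normal draw around
    the program's mean effect (plus any subgroup bonus on the program's
    designated subdimension), truncated so post-scores stay in [0, 100].
    """
    if program not in PROGRAMS:
        raise ValueError(f"unknown program {program!r}")
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    pre_norm = profile.burnout_normalized(spec.schema)
    dominant = dominant_subdimension(pre_norm)
    het_bonus = _bonus_by_subdimension(spec, profile, program, dominant)
    post_norm: dict[str, float] = {}
    for sub in SUBDIMENSIONS:
        mean, sd = spec.response_model[program][sub]
        mean = mean + het_bonus.get(sub, 0.0)
        drop = rng.normal(mean, sd) if sd > 0 else mean
        post_norm[sub] = float(np.clip(pre_norm[sub] - drop, 0.0, 100.0))
    matched = subgroup_best_program(spec, profile) == program
    sat_mean = spec.satisfaction_base + (
        spec.satisfaction_match_bonus if matched else 0.0
    )
    sat_draw = (
        rng.normal(sat_mean, spec.satisfaction_sd)
        if spec.satisfaction_sd > 0
        else sat_mean
    )
    satisfaction = int(np.clip(round(sat_draw), 1, 5))
    return ProgramOutcome(
        program=program,
        pre=BurnoutScores.from_normalized(
            pre_norm["personal"], pre_norm["work"], pre_norm["client"]
        ),
        post=BurnoutScores.from_normalized(
            post_norm["personal"], post_norm["work"], post_norm["client"]
        ),
        satisfaction=satisfaction,
    )


# -- closed-loop replay --------------------------------------------------


@dataclass
class TrialResult:
    """Tidy per-participant-stage record of one closed-loop run."""

    table: pd.DataFrame
    kb: KnowledgeBase
    policy: str

    @property
    def n_valid(self) -> int:
        return int(self.table["valid"].sum())


def _policy_choice(
    policy: str,
    recommender: ProgramRecommender,
    profile: ParticipantProfile,
    stage: int,
    exclude: set[str],
    spec: CohortSpec,
    rng: np.random.Generator,
):
    """Program for one stage under the given allocation policy."""
    if policy == "similarity":
        rec = recommender.recommend(profile, stage=stage, exclude=exclude)
        return rec.program, rec
    available = [p for p in PROGRAMS if p not in exclude]
    if policy == "random":
        return available[rng.choice(len(available))], None
    if policy.startswith("fixed"):
        prog = policy.split(":", 1)[1] if ":" in policy else "laughter"
        if prog not in PROGRAMS:
            raise ValueError(f"unknown fixed program {prog!r}")
        if prog in exclude:
            prog = next(p for p in DEFAULT_FALLBACK_ORDER if p not in exclude)
        return prog, None
    if policy == "oracle":
        if spec.heterogeneity is not None:
            dominant = dominant_subdimension(profile.burnout_normalized(spec.schema))
            bonuses = _subgroup_bonuses(spec, profile, dominant)
            scored = sorted(
                available, key=lambda p: bonuses.get(p, 0.0), reverse=True
            )
            if scored:
                return scored[0], None
        # no subgroup truth: largest expected total-scale reduction
        def total_effect(p: str) -> float:
            from .schema import SUBDIM_MAX

            return sum(
                spec.response_model[p][s][0] * SUBDIM_MAX[s] / 100.0
                for s in SUBDIMENSIONS
            )

        return max(available, key=total_effect), None
    raise ValueError(f"unknown policy {policy!r}")


def run_closed_loop_trial(
    spec: CohortSpec,
    policy: str = "similarity",
    initial_kb: KnowledgeBase | None = None,
    seed: int | np.random.Generator | None = None,
    id_prefix: str = "P",
) -> TrialResult:
    """Replay the sequential two-stage trial under an allocation policy.

    Participants are processed in order; each stage runs recommendation,
    simulated response, the validity screen, and (when valid) an
    append-only knowledge-base update, so later participants benefit
    from earlier data exactly as in deployment.
    """
    rng = (
        seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    )
    kb = initial_kb if initial_kb is not None else KnowledgeBase(spec.schema)
    recommender = ProgramRecommender(schema=spec.schema).fit(kb)
    rows: list[dict] = []
    for order in range(1, spec.n + 1):
        profile = sample_participant(spec, f"{id_prefix}{order:04d}", rng)
        if spec.dropout_rate and rng.random() < spec.dropout_rate:
            continue
        exclude: set[str] = set()
        current = profile
        for stage in (1, 2):
            best = subgroup_best_program(spec, current)
            program, rec = _policy_choice(
                policy, recommender, current, stage, exclude, spec, rng
            )
            outcome = simulate_response(current, program, spec, rng)
            reductions = subdimension_reductions(outcome.pre, outcome.post)
            result = classify_validity(reductions)
            if result.valid:
                sub = result.effective_subdimension
                kb.append(
                    ValidRecord(
                        profile=current,
                        program=program,
                        effective_subdimension=sub,
                        reduction=reductions[sub],
                    )
                )
            pre_n = outcome.pre.normalized
            post_n = outcome.post.normalized
            rows.append(
                {
                    "participant_id": profile.participant_id,
                    "order": order,
                    "stage": stage,
                    "program": program,
                    "dominant_subdimension": dominant_subdimension(
                        current.burnout_normalized(spec.schema)
                    ),
                    "stratum": _stratum(spec, profile),
                    "subgroup_best": best,
                    "cold_start": bool(rec.cold_start) if rec is not None else False,
                    "dissimilarity": rec.dissimilarity if rec is not None else None,
                    "pre_total": outcome.pre.total,
                    "post_total": outcome.post.total,
                    "reduction_total": outcome.pre.total - outcome.post.total,
                    **{f"pre_{s}": pre_n[s] for s in SUBDIMENSIONS},
                    **{f"post_{s}": post_n[s] for s in SUBDIMENSIONS},
                    "valid": result.valid,
                    "effective_subdimension": result.effective_subdimension,
                    "satisfaction": outcome.satisfaction,
                }
            )
            current = current.with_burnout(
                spec.schema,
                {s: post_n[s] for s in SUBDIMENSIONS},
                "posttest1" if stage == 1 else "posttest2",
            )
            exclude.add(program)
    table = pd.DataFrame(rows)
    return TrialResult(table=table, kb=kb, policy=policy)


def subgroup_match_rate(
    trial: TrialResult, stage: int = 1, tail: float = 1.0 / 3.0
) -> float:
    """Fraction of late-cohort stage assignments hitting the subgroup-best program.

    ``tail`` selects the final fraction of the cohort by participation
    order (default: the last third, where the knowledge base is mature).
    """
    t = trial.table
    t = t[(t["stage"] == stage) & t["subgroup_best"].notna()]
    if t.empty:
        raise ValueError("trial has no subgroup structure")
    cutoff = t["order"].max() - tail * (t["order"].max() - t["order"].min() + 1)
    late = t[t["order"] > cutoff]
    return float((late["program"] == late["subgroup_best"]).mean())
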