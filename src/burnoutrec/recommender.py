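"""Two-stage tailored program recommendation over an accumulating knowledge base.

The engine is a user-based nearest-neighbor recommender.  At each stage
it (1) determines the participant's dominant burnout subdimension,
(2) filters stored valid records to those whose effective subdimension
matches, (3) returns the program of the record with the lowest profile
dissimilarity.  When the matching filter empties the candidate set the
search falls back to the unfiltered knowledge base; with no usable
records at all a configurable cold-start preallocation maps the dominant
subdimension to a program.  Stage 2 repeats the procedure on the
post-program-1 profile, restricted to the three remaining programs.

:class:`ProgramRecommender` packages this as a scikit-learn-style
estimator (``fit`` / ``partial_fit`` on valid records, ``predict`` on
profiles); the module-level functions are thin wrappers over it.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

from sklearn.base import BaseEstimator

from .schema import (
    PROGRAMS,
    SUBDIMENSIONS,
    BurnoutScores,
    FeatureSchema,
    KnowledgeBase,
    ParticipantProfile,
    ValidRecord,
    default_schema,
)
from .similarity import DissimilarityBreakdown, profile_dissimilarity, rank_records

__all__ = [
    "Recommendation",
    "AuditReport",
    "ProgramRecommender",
    "dominant_subdimension",
    "cold_start_allocation",
    "recommend_stage1",
    "recommend_stage2",
    "update_knowledge_base",
    "audit_recommendation",
    "DEFAULT_COLD_START_MAP",
    "DEFAULT_FALLBACK_ORDER",
    "DEFAULT_TIE_PRIORITY",
]

#: Preallocation used when no valid records are available.  The mapping
#: is a configuration choice, not a property of the method.
DEFAULT_COLD_START_MAP = {
    "personal": "mindfulness",
    "work": "storytelling",
    "client": "act",
}

#: Order in which programs are tried when the mapped one is excluded.
DEFAULT_FALLBACK_ORDER = ("laughter", "mindfulness", "storytelling", "act")

#: Tie-break priority for the dominant subdimension.
DEFAULT_TIE_PRIORITY = ("work", "client", "personal")


@dataclass(frozen=True)
class Recommendation:
    """One program recommendation with its provenance."""

    program: str
    stage: int
    matched_record: ValidRecord | None = None
    dissimilarity: float | None = None
    cold_start: bool = False
    #: "matched" (subdimension filter applied), "all" (fallback to the
    #: unfiltered KB) or "cold_start"
    candidate_pool: str = "matched"
    audit: DissimilarityBreakdown | None = None


@dataclass(frozen=True)
class AuditReport:
    """Full ranked candidate table backing one recommendation.

    Reproduces the manual verification workflow: every eligible record
    with its total dissimilarity and per-element breakdown, ascending,
    with the top row equal to the recommendation.
    """

    stage: int
    recommendation: Recommendation
    rows: tuple[tuple[ValidRecord, float, DissimilarityBreakdown], ...]


def dominant_subdimension(
    scores: BurnoutScores | Mapping[str, float],
    priority: Sequence[str] = DEFAULT_TIE_PRIORITY,
) -> str:
    """Subdimension with the highest normalized score; ties broken by priority."""
    if isinstance(scores, BurnoutScores):
        norm = scores.normalized
    else:
        norm = {s: float(scores[s]) for s in SUBDIMENSIONS}
    best = max(norm.values())
    for sub in priority:
        if norm[sub] == best:
            return sub
    raise ValueError(f"priority {priority!r} does not cover subdimensions {SUBDIMENSIONS}")


def cold_start_allocation(
    dominant: str,
    excluded: Iterable[str] = (),
    cold_start_map: Mapping[str, str] = DEFAULT_COLD_START_MAP,
    fallback_order: Sequence[str] = DEFAULT_FALLBACK_ORDER,
) -> str:
    """Preallocated program for a dominant subdimension, skipping exclusions."""
    excluded = set(excluded)
    if not excluded <= set(PROGRAMS):
        raise ValueError(f"unknown excluded programs: {sorted(excluded - set(PROGRAMS))}")
    if excluded >= set(PROGRAMS):
        raise ValueError("all programs excluded; no cold-start allocation possible")
    mapped = cold_start_map[dominant]
    if mapped not in excluded:
        return mapped
    for prog in fallback_order:
        if prog not in excluded:
            return prog
    raise ValueError("fallback order exhausted")  # unreachable: excluded < PROGRAMS


class ProgramRecommender(BaseEstimator):
    """Nearest-profile program recommender with incremental updates.

    Parameters
    ----------
    schema : FeatureSchema, optional
        Feature schema; the shipped 5 + 17 default if omitted.
    cold_start_map : mapping subdimension -> program
    fallback_order : sequence of programs tried when the mapped cold-start
        program is excluded.
    tie_priority : dominance tie-break order over subdimensions.

    Attributes
    ----------
    knowledge_base_ : KnowledgeBase
        The accumulated valid records, set by :meth:`fit` /
        :meth:`partial_fit`.
    """

    def __init__(
        self,
        schema: FeatureSchema | None = None,
        cold_start_map: Mapping[str, str] | None = None,
        fallback_order: Sequence[str] | None = None,
        tie_priority: Sequence[str] | None = None,
    ) -> None:
        self.schema = schema
        self.cold_start_map = cold_start_map
        self.fallback_order = fallback_order
        self.tie_priority = tie_priority

    # -- config resolution ----------------------------------------------

    def _resolved_schema(self) -> FeatureSchema:
        return self.schema if self.schema is not None else default_schema()

    @property
    def _cold_start_map(self) -> Mapping[str, str]:
        return self.cold_start_map or DEFAULT_COLD_START_MAP

    @property
    def _fallback_order(self) -> Sequence[str]:
        return self.fallback_order or DEFAULT_FALLBACK_ORDER

    @property
    def _tie_priority(self) -> Sequence[str]:
        return self.tie_priority or DEFAULT_TIE_PRIORITY

    # -- fitting ---------------------------------------------------------

    def fit(self, records: Iterable[ValidRecord] | KnowledgeBase, y=None) -> "ProgramRecommender":
        """Initialize the knowledge base from valid records (may be empty)."""
        if isinstance(records, KnowledgeBase):
            self.knowledge_base_ = records
        else:
            self.knowledge_base_ = KnowledgeBase(self._resolved_schema(), records)
        return self

    def partial_fit(
        self, records: Iterable[ValidRecord], y=None
    ) -> "ProgramRecommender":
        """Append new valid records, preserving existing order (append-only)."""
        if not hasattr(self, "knowledge_base_"):
            return self.fit(records)
        self.knowledge_base_.extend(records)
        return self

    def _check_fitted(self) -> KnowledgeBase:
        if not hasattr(self, "knowledge_base_"):
            raise RuntimeError("recommender is not fitted; call fit() first")
        return self.knowledge_base_

    # -- recommendation --------------------------------------------------

    def _dominant(self, profile: ParticipantProfile) -> str:
        scores = profile.burnout_normalized(self._check_fitted().schema)
        return dominant_subdimension(scores, self._tie_priority)

    def recommend(
        self,
        profile: ParticipantProfile,
        stage: int = 1,
        exclude: Iterable[str] = (),
        audit: bool = False,
    ) -> Recommendation:
        """Recommend a program for one profile.

        ``stage=2`` recomputes dominance from the given (post-program-1)
        profile and must exclude the stage-1 program via ``exclude``.
        """
        kb = self._check_fitted()
        vars = kb.schema.stage_vars(stage)
        excluded = set(exclude)
        dominant = self._dominant(profile)

        def eligible(r: ValidRecord) -> bool:
            return r.program not in excluded

        ranked = rank_records(
            kb,
            profile,
            vars,
            lambda r: eligible(r) and r.effective_subdimension == dominant,
        )
        pool = "matched"
        if not ranked:
            ranked = rank_records(kb, profile, vars, eligible)
            pool = "all"
        if not ranked:
            program = cold_start_allocation(
                dominant, excluded, self._cold_start_map, self._fallback_order
            )
            return Recommendation(
                program=program, stage=stage, cold_start=True, candidate_pool="cold_start"
            )
        best, total = ranked[0]
        breakdown = (
            profile_dissimilarity(best.profile, profile, kb.schema, vars)
            if audit
            else None
        )
        return Recommendation(
            program=best.program,
            stage=stage,
            matched_record=best,
            dissimilarity=total,
            candidate_pool=pool,
            audit=breakdown,
        )

    def predict(
        self, profiles: Sequence[ParticipantProfile], stage: int = 1
    ) -> list[str]:
        """Program id per profile (scikit-learn predict surface)."""
        return [self.recommend(p, stage=stage).program for p in profiles]

    def audit(
        self,
        profile: ParticipantProfile,
        stage: int = 1,
        exclude: Iterable[str] = (),
    ) -> AuditReport:
        """Ranked candidate table with per-element breakdowns.

        Makes the recommendation manually verifiable: the report lists
        every eligible record ascending by dissimilarity and its top row
        equals the output of :meth:`recommend`.
        """
        kb = self._check_fitted()
        vars = kb.schema.stage_vars(stage)
        excluded = set(exclude)
        dominant = self._dominant(profile)

        def eligible(r: ValidRecord) -> bool:
            return r.program not in excluded

        ranked = rank_records(
            kb,
            profile,
            vars,
            lambda r: eligible(r) and r.effective_subdimension == dominant,
        )
        if not ranked:
            ranked = rank_records(kb, profile, vars, eligible)
        rows = tuple(
            (rec, total, profile_dissimilarity(rec.profile, profile, kb.schema, vars))
            for rec, total in ranked
        )
        rec = self.recommend(profile, stage=stage, exclude=excluded, audit=True)
        return AuditReport(stage=stage, recommendation=rec, rows=rows)


# -- module-level wrappers ----------------------------------------------


def _fitted(kb: KnowledgeBase, **params) -> ProgramRecommender:
    return ProgramRecommender(schema=kb.schema, **params).fit(kb)


def recommend_stage1(
    kb: KnowledgeBase, new: ParticipantProfile, **params
) -> Recommendation:
    """Stage-1 recommendation from a pretest profile."""
    return _fitted(kb, **params).recommend(new, stage=1)


def recommend_stage2(
    kb: KnowledgeBase, new: ParticipantProfile, program1: str, **params
) -> Recommendation:
    """Stage-2 recommendation from a posttest-1 profile, excluding program 1."""
    if program1 not in PROGRAMS:
        raise ValueError(f"unknown program {program1!r}")
    rec = _fitted(kb, **params).recommend(new, stage=2, exclude={program1})
    assert rec.program != program1
    return rec


def update_knowledge_base(
    kb: KnowledgeBase, new_records: Iterable[ValidRecord]
) -> KnowledgeBase:
    """Append new valid records; existing records and order are untouched."""
    kb.extend(new_records)
    return kb


def audit_recommendation(
    kb: KnowledgeBase,
    new: ParticipantProfile,
    stage: int = 1,
    exclude: Iterable[str] = (),
    **params,
) -> AuditReport:
    """Ranked candidate report for a recommendation (manual-check workflow)."""
    return _fitted(kb, **params).audit(new, stage=stage, exclude=exclude)
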