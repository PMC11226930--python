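"""Valid-data screening for completed program stages.

A program stage counts as *valid* — evidence that the program itself
lowered burnout — when exactly one CBI subdimension dropped by at least
5 points on the normalized 0–100 scale.  A drop of 5+ points in two or
more subdimensions is attributed to causes other than the program and
the stage is discarded; no 5-point drop at all means the program was
ineffective for that participant.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping

from .schema import (
    SUBDIMENSIONS,
    VALID_REDUCTION_THRESHOLD,
    BurnoutScores,
    ParticipantProfile,
    ProgramOutcome,
    ValidRecord,
)

__all__ = [
    "ValidityResult",
    "subdimension_reductions",
    "classify_validity",
    "extract_valid_records",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ValidityResult:
    """Outcome of the validity screen for one program stage."""

    valid: bool
    effective_subdimension: str | None = None
    reason: str | None = None  # "multi_dimension" | "insufficient_reduction"


def _as_normalized(scores: BurnoutScores | Mapping[str, float]) -> dict[str, float]:
    if isinstance(scores, BurnoutScores):
        return scores.normalized
    missing = set(SUBDIMENSIONS) - set(scores)
    if missing:
        raise ValueError(f"missing subdimension scores: {sorted(missing)}")
    return {s: float(scores[s]) for s in SUBDIMENSIONS}


def subdimension_reductions(
    pre: BurnoutScores | Mapping[str, float],
    post: BurnoutScores | Mapping[str, float],
) -> dict[str, float]:
    """Per-subdimension reduction ``pre - post`` on the normalized scale.

    Positive values mean improvement; worsening yields a negative
    reduction, which is allowed.
    """
    p = _as_normalized(pre)
    q = _as_normalized(post)
    return {s: p[s] - q[s] for s in SUBDIMENSIONS}


def classify_validity(reductions: Mapping[str, float]) -> ValidityResult:
    """Apply the single-subdimension >= 5-point rule to a reduction triple."""
    missing = set(SUBDIMENSIONS) - set(reductions)
    if missing:
        raise ValueError(f"missing reductions for: {sorted(missing)}")
    hits = [s for s in SUBDIMENSIONS if reductions[s] >= VALID_REDUCTION_THRESHOLD]
    if len(hits) == 1:
        return ValidityResult(valid=True, effective_subdimension=hits[0])
    if len(hits) >= 2:
        return ValidityResult(valid=False, reason="multi_dimension")
    return ValidityResult(valid=False, reason="insufficient_reduction")


def extract_valid_records(
    history: Iterable[tuple[ParticipantProfile, ProgramOutcome]],
) -> list[ValidRecord]:
    """Screen a (pre-assessment profile, outcome) history into valid records.

    Each element pairs a program outcome with the participant's profile
    at the assessment *preceding* that program (pretest for stage 1,
    posttest 1 for stage 2).  Both of a participant's stages may
    independently yield a record.  Insertion indices are left unset;
    the knowledge base assigns them on append.
    """
    out: list[ValidRecord] = []
    for profile, outcome in history:
        if profile is None:
            raise ValueError("program outcome missing its preceding assessment profile")
        reductions = subdimension_reductions(outcome.pre, outcome.post)
        result = classify_validity(reductions)
        if not result.valid:
            logger.debug(
                "stage invalid (%s): participant=%s program=%s",
                result.reason,
                profile.participant_id,
                outcome.program,
            )
            continue
        sub = result.effective_subdimension
        assert sub is not None
        out.append(
            ValidRecord(
                profile=profile,
                program=outcome.program,
                effective_subdimension=sub,
                reduction=reductions[sub],
            )
        )
    return out
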