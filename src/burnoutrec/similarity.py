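"""Mixed-type profile dissimilarity and nearest-record search.

Dissimilarity between an existing user *i* and a new user *j* is the sum
of per-variable contributions:

* categorical variable: 0 if the codes match, 1 otherwise;
* numerical variable with range R: ``|x_i - x_j| / R``, clipped to [0, 1].

Contributions are unit-weighted, so the total lies in ``[0, n_vars]``
(0–22 for the default 5 + 17 schema).  Lower totals mean more similar
profiles; the nearest stored record drives the recommendation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Callable, Mapping, Sequence

import numpy as np

from .schema import (
    FeatureSchema,
    KnowledgeBase,
    NumericalVar,
    ParticipantProfile,
    ValidRecord,
)

__all__ = [
    "DissimilarityBreakdown",
    "categorical_element_dissimilarity",
    "numerical_element_dissimilarity",
    "profile_dissimilarity",
    "rank_records",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class DissimilarityBreakdown:
    """Per-variable contributions and their sum for one profile pair."""

    per_element: Mapping[str, float]
    total: float

    @classmethod
    def from_elements(cls, per_element: Mapping[str, float]) -> "DissimilarityBreakdown":
        return cls(per_element=dict(per_element), total=float(sum(per_element.values())))


def categorical_element_dissimilarity(a, b, codes: Sequence | None = None) -> float:
    """0 for matching codes, 1 for a mismatch.

    If ``codes`` is given, both values must belong to the allowed set.
    """
    if codes is not None:
        for v in (a, b):
            if v not in codes:
                raise ValueError(f"code {v!r} not in allowed set {tuple(codes)!r}")
    return 0.0 if a == b else 1.0


def numerical_element_dissimilarity(
    a: float, b: float, R: float, degenerate: bool = False
) -> float:
    """Range-scaled absolute difference ``|a - b| / R``, clipped to [0, 1].

    A degenerate variable (zero range) falls back to the equality rule.
    """
    if degenerate or R == 0:
        if not degenerate:
            raise ValueError("range R must be positive for a non-degenerate variable")
        return 0.0 if a == b else 1.0
    if R < 0:
        raise ValueError(f"range R must be positive, got {R}")
    d = abs(float(a) - float(b)) / float(R)
    if d > 1.0:
        logger.warning(
            "element difference %s exceeds variable range %s; clipping contribution at 1",
            abs(a - b),
            R,
        )
        return 1.0
    return d


def _element(
    schema: FeatureSchema, name: str, p: ParticipantProfile, q: ParticipantProfile
) -> float:
    if schema.is_categorical(name):
        var = schema.categorical_var(name)
        try:
            a = p.categorical_values[name]
            b = q.categorical_values[name]
        except KeyError as exc:
            raise ValueError(f"profile missing variable {name!r}") from exc
        return categorical_element_dissimilarity(a, b, var.codes)
    var = schema.numerical_var(name)
    try:
        a = p.numerical_values[name]
        b = q.numerical_values[name]
    except KeyError as exc:
        raise ValueError(f"profile missing variable {name!r}") from exc
    return numerical_element_dissimilarity(a, b, var.range, var.degenerate)


def profile_dissimilarity(
    existing: ParticipantProfile,
    new: ParticipantProfile,
    schema: FeatureSchema,
    vars: Sequence[str] | None = None,
) -> DissimilarityBreakdown:
    """Summed per-variable dissimilarity between two profiles.

    Symmetric in its two profile arguments.  ``vars`` restricts the
    comparison to a stage subset; by default every schema variable
    contributes.
    """
    names = tuple(vars) if vars is not None else schema.variable_names
    per = {name: _element(schema, name, existing, new) for name in names}
    return DissimilarityBreakdown.from_elements(per)


def _stage_columns(
    schema: FeatureSchema, vars: Sequence[str]
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Column indices + range vector for a stage subset, in schema order."""
    names = set(vars)
    cat_idx = np.array(
        [i for i, v in enumerate(schema.categorical) if v.name in names], dtype=int
    )
    num_idx = np.array(
        [i for i, v in enumerate(schema.numerical) if v.name in names], dtype=int
    )
    ranges = np.array([schema.numerical[i].range for i in num_idx], dtype=float)
    degen = ranges == 0
    return cat_idx, num_idx, ranges, degen


def rank_records(
    kb: KnowledgeBase,
    new: ParticipantProfile,
    vars: Sequence[str] | None = None,
    candidate_filter: Callable[[ValidRecord], bool] | None = None,
) -> list[tuple[ValidRecord, float]]:
    """Rank knowledge-base records by ascending dissimilarity to a profile.

    Ties are broken by lower insertion index (the earliest stored valid
    record), making the ranking deterministic and auditable.  An empty
    candidate set yields an empty list — the caller's cold-start signal.
    """
    schema = kb.schema
    names = tuple(vars) if vars is not None else schema.variable_names
    records = list(kb)
    if candidate_filter is not None:
        keep = [i for i, r in enumerate(records) if candidate_filter(r)]
    else:
        keep = list(range(len(records)))
    if not keep:
        return []

    cat_idx, num_idx, ranges, degen = _stage_columns(schema, names)
    cat_all, num_all = kb.feature_matrices()
    cat = cat_all[np.ix_(keep, cat_idx)] if cat_idx.size else None
    num = num_all[np.ix_(keep, num_idx)] if num_idx.size else None

    totals = np.zeros(len(keep), dtype=float)
    if cat is not None:
        new_cat = np.array(
            [new.categorical_values[schema.categorical[i].name] for i in cat_idx],
            dtype=object,
        )
        totals += (cat != new_cat).sum(axis=1).astype(float)
    if num is not None:
        new_num = np.array(
            [new.numerical_values[schema.numerical[i].name] for i in num_idx],
            dtype=float,
        )
        diff = np.abs(num - new_num)
        with np.errstate(divide="ignore", invalid="ignore"):
            contrib = np.where(degen, (diff != 0).astype(float), diff / ranges)
        totals += np.minimum(contrib, 1.0).sum(axis=1)

    order = sorted(
        range(len(keep)), key=lambda i: (totals[i], records[keep[i]].insertion_index)
    )
    return [(records[keep[i]], float(totals[i])) for i in order]
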