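"""Persistent stores: participant CSV tables and the JSON-lines knowledge base.

CSV holds one row per participant per assessment point (tidy layout);
the knowledge base is JSON lines, one valid record per line, matching
its append-only update semantics.
"""

from __future__ import annotations

from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

from .schema import (
    FeatureSchema,
    KnowledgeBase,
    ParticipantProfile,
    ProfileError,
)

__all__ = [
    "read_participants",
    "write_participants",
    "read_kb",
    "write_kb",
    "ParticipantReadError",
]


class ParticipantReadError(ValueError):
    """Raised when participant rows fail validation; carries row errors."""

    def __init__(self, errors: list[tuple[int, str]]):
        self.errors = errors
        detail = "; ".join(f"row {i}: {msg}" for i, msg in errors[:5])
        more = f" (+{len(errors) - 5} more)" if len(errors) > 5 else ""
        super().__init__(f"{len(errors)} invalid participant row(s): {detail}{more}")


def _coerce_code(value, codes: Sequence):
    """Coerce a CSV cell to the type used by the schema's allowed codes."""
    if value in codes:
        return value
    for code in codes:
        try:
            if type(code)(value) == code:
                return code
        except (TypeError, ValueError):
            continue
    return value  # leave as-is; validation will name the offender


def read_participants(
    path: str | Path, schema: FeatureSchema, strict: bool = True
) -> list[ParticipantProfile]:
    """Load validated profiles from a participant CSV.

    Expected columns: ``participant_id``, ``assessment_point``, plus one
    column per schema variable.  In strict mode any bad row aborts the
    load with a :class:`ParticipantReadError` naming the rows; otherwise
    bad rows are collected on the returned error list attribute and
    skipped.
    """
    df = pd.read_csv(path, float_precision="round_trip")
    if df.empty and not set(schema.variable_names) <= set(df.columns):
        return []
    required = {"participant_id", "assessment_point", *schema.variable_names}
    missing = required - set(df.columns)
    if missing:
        raise ParticipantReadError([(0, f"missing columns: {sorted(missing)}")])
    unknown = set(df.columns) - required
    if unknown:
        raise ParticipantReadError([(0, f"unknown columns: {sorted(unknown)}")])

    profiles: list[ParticipantProfile] = []
    errors: list[tuple[int, str]] = []
    for i, row in df.iterrows():
        rownum = int(i) + 2  # header is line 1
        try:
            cat = {
                v.name: _coerce_code(row[v.name], v.codes) for v in schema.categorical
            }
            num = {v.name: float(row[v.name]) for v in schema.numerical}
            profile = ParticipantProfile(
                participant_id=str(row["participant_id"]),
                categorical_values=cat,
                numerical_values=num,
                assessment_point=str(row["assessment_point"]),
            )
            schema.validate_profile(profile)
            profiles.append(profile)
        except (ProfileError, ValueError, TypeError) as exc:
            errors.append((rownum, str(exc)))
    if errors and strict:
        raise ParticipantReadError(errors)
    return profiles


def write_participants(
    profiles: Iterable[ParticipantProfile], path: str | Path, schema: FeatureSchema
) -> None:
    """Write profiles to CSV, one row per participant-assessment."""
    rows = []
    for p in profiles:
        row = {
            "participant_id": p.participant_id,
            "assessment_point": p.assessment_point,
        }
        row.update({v.name: p.categorical_values[v.name] for v in schema.categorical})
        row.update({v.name: p.numerical_values[v.name] for v in schema.numerical})
        rows.append(row)
    columns = ["participant_id", "assessment_point", *schema.variable_names]
    pd.DataFrame(rows, columns=columns).to_csv(path, index=False)


def read_kb(path: str | Path, schema: FeatureSchema) -> KnowledgeBase:
    """Load a knowledge base from JSON lines, preserving insertion order.

    A corrupt or invariant-violating line (e.g. reduction below the
    5-point threshold) aborts with the offending line number.
    """
    return KnowledgeBase.from_jsonl(path, schema)


def write_kb(kb: KnowledgeBase, path: str | Path) -> None:
    """Write a knowledge base as JSON lines, one record per line."""
    kb.to_jsonl(path)
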