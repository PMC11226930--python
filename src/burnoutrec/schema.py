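"""Data model for the tailored burnout-program recommender.

The engine operates on mixed-type participant profiles: a fixed set of
categorical variables (compared by equality) and numerical variables
(compared by range-scaled absolute difference).  The default schema has
5 categorical and 17 numerical variables, so the maximum attainable
profile dissimilarity is 22.

Burnout is scored on the Copenhagen Burnout Inventory (CBI): three
subdimensions — personal (0–31.5), work-related (0–37), client-related
(0–31.5) — whose raw scores sum to the 0–100 total.  All validity and
matching logic runs on the normalized 0–100 per-subdimension scale
(raw / subdomain max * 100).
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Any, Iterable, Iterator, Mapping, Sequence

import numpy as np
import yaml

__all__ = [
    "PROGRAMS",
    "SUBDIMENSIONS",
    "SUBDIM_MAX",
    "VALID_REDUCTION_THRESHOLD",
    "ASSESSMENT_POINTS",
    "CategoricalVar",
    "NumericalVar",
    "FeatureSchema",
    "ParticipantProfile",
    "BurnoutScores",
    "ValidRecord",
    "KnowledgeBase",
    "ProgramOutcome",
    "load_schema",
    "default_schema",
    "normalize_burnout",
]

#: The four candidate intervention programs.
PROGRAMS = ("mindfulness", "storytelling", "laughter", "act")

#: CBI subdimensions, in canonical (personal, work, client) order.
SUBDIMENSIONS = ("personal", "work", "client")

#: Maximum raw score of each CBI subdomain; the three maxima sum to 100.
SUBDIM_MAX = {"personal": 31.5, "work": 37.0, "client": 31.5}

#: Minimum normalized-scale reduction for a program stage to count as valid.
VALID_REDUCTION_THRESHOLD = 5.0

ASSESSMENT_POINTS = ("pretest", "posttest1", "posttest2")


class SchemaError(ValueError):
    """Raised for an invalid schema configuration."""


class ProfileError(ValueError):
    """Raised for a profile that violates its schema."""


@dataclass(frozen=True)
class CategoricalVar:
    """A categorical variable: opaque codes compared by equality only."""

    name: str
    codes: tuple

    def __post_init__(self) -> None:
        if len(self.codes) == 0:
            raise SchemaError(f"categorical variable {self.name!r} has no codes")
        if len(set(self.codes)) != len(self.codes):
            raise SchemaError(f"categorical variable {self.name!r} has overlapping codes")


@dataclass(frozen=True)
class NumericalVar:
    """A numerical variable with a fixed theoretical range.

    The range ``R = vmax - vmin`` scales the element dissimilarity.  A
    variable with ``vmin == vmax`` is flagged degenerate and compared by
    equality instead.
    """

    name: str
    vmin: float
    vmax: float

    def __post_init__(self) -> None:
        if math.isnan(self.vmin) or math.isnan(self.vmax):
            raise SchemaError(f"numerical variable {self.name!r} has NaN bounds")
        if self.vmax < self.vmin:
            raise SchemaError(f"numerical variable {self.name!r} has vmax < vmin")

    @property
    def range(self) -> float:
        return self.vmax - self.vmin

    @property
    def degenerate(self) -> bool:
        return self.range == 0


@dataclass(frozen=True)
class FeatureSchema:
    """Declares the variables of a participant profile.

    Parameters
    ----------
    categorical, numerical
        Ordered variable descriptors.
    stage1_vars, stage2_vars
        Variable subsets used by the first- and second-stage
        recommendation.  Stage 2 is restricted to demographics / work
        characteristics plus the burnout subdimensions.
    burnout_vars
        Mapping from CBI subdimension to the (normalized, 0–100)
        numerical variable carrying it in the profile.
    """

    categorical: tuple[CategoricalVar, ...]
    numerical: tuple[NumericalVar, ...]
    stage1_vars: tuple[str, ...] = ()
    stage2_vars: tuple[str, ...] = ()
    burnout_vars: Mapping[str, str] = field(
        default_factory=lambda: {
            "personal": "burnout_personal",
            "work": "burnout_work",
            "client": "burnout_client",
        }
    )

    def __post_init__(self) -> None:
        names = [v.name for v in self.categorical] + [v.name for v in self.numerical]
        if not names:
            raise SchemaError("schema declares no variables")
        dupes = {n for n in names if names.count(n) > 1}
        if dupes:
            raise SchemaError(f"duplicate variable names: {sorted(dupes)}")
        if not self.stage1_vars:
            object.__setattr__(self, "stage1_vars", tuple(names))
        if not self.stage2_vars:
            object.__setattr__(self, "stage2_vars", tuple(names))
        known = set(names)
        for stage, subset in (("stage1", self.stage1_vars), ("stage2", self.stage2_vars)):
            unknown = set(subset) - known
            if unknown:
                raise SchemaError(f"{stage}_vars reference unknown variables: {sorted(unknown)}")
        if not set(self.stage2_vars) <= set(self.stage1_vars):
            raise SchemaError("stage2_vars must be a subset of stage1_vars")

    # -- lookups ---------------------------------------------------------

    @property
    def variable_names(self) -> tuple[str, ...]:
        return tuple(v.name for v in self.categorical) + tuple(v.name for v in self.numerical)

    @property
    def n_variables(self) -> int:
        return len(self.categorical) + len(self.numerical)

    @property
    def max_dissimilarity(self) -> float:
        """Largest attainable profile dissimilarity: one unit per variable."""
        return float(self.n_variables)

    def categorical_var(self, name: str) -> CategoricalVar:
        for v in self.categorical:
            if v.name == name:
                return v
        raise KeyError(name)

    def numerical_var(self, name: str) -> NumericalVar:
        for v in self.numerical:
            if v.name == name:
                return v
        raise KeyError(name)

    def is_categorical(self, name: str) -> bool:
        return any(v.name == name for v in self.categorical)

    def stage_vars(self, stage: int) -> tuple[str, ...]:
        if stage == 1:
            return self.stage1_vars
        if stage == 2:
            return self.stage2_vars
        raise ValueError(f"stage must be 1 or 2, got {stage!r}")

    # -- validation ------------------------------------------------------

    def validate_profile(self, profile: "ParticipantProfile") -> None:
        """Raise :class:`ProfileError` if the profile violates the schema."""
        for v in self.categorical:
            if v.name not in profile.categorical_values:
                raise ProfileError(f"missing categorical variable {v.name!r}")
            code = profile.categorical_values[v.name]
            if code not in v.codes:
                raise ProfileError(
                    f"{v.name!r}: code {code!r} not in allowed set {v.codes!r}"
                )
        for v in self.numerical:
            if v.name not in profile.numerical_values:
                raise ProfileError(f"missing numerical variable {v.name!r}")
            x = profile.numerical_values[v.name]
            if not (v.vmin <= x <= v.vmax):
                raise ProfileError(
                    f"{v.name!r}: value {x} outside [{v.vmin}, {v.vmax}]"
                )
        extra = (
            set(profile.categorical_values) - {v.name for v in self.categorical}
        ) | (set(profile.numerical_values) - {v.name for v in self.numerical})
        if extra:
            raise ProfileError(f"unknown variables in profile: {sorted(extra)}")

    def to_config(self) -> dict:
        """Serializable configuration dict (inverse of :func:`load_schema`)."""
        return {
            "variables": [
                *(
                    {"name": v.name, "kind": "categorical", "codes": list(v.codes)}
                    for v in self.categorical
                ),
                *(
                    {"name": v.name, "kind": "numerical", "min": v.vmin, "max": v.vmax}
                    for v in self.numerical
                ),
            ],
            "stage1_vars": list(self.stage1_vars),
            "stage2_vars": list(self.stage2_vars),
            "burnout_vars": dict(self.burnout_vars),
        }


@dataclass(frozen=True)
class ParticipantProfile:
    """One participant's feature vector at a given assessment point."""

    participant_id: str
    categorical_values: Mapping[str, Any]
    numerical_values: Mapping[str, float]
    assessment_point: str = "pretest"

    def __post_init__(self) -> None:
        if self.assessment_point not in ASSESSMENT_POINTS:
            raise ProfileError(
                f"assessment_point must be one of {ASSESSMENT_POINTS}, "
                f"got {self.assessment_point!r}"
            )

    def burnout_normalized(self, schema: FeatureSchema) -> dict[str, float]:
        """Normalized (0–100) burnout subdimension scores stored in the profile."""
        return {
            sub: float(self.numerical_values[var])
            for sub, var in schema.burnout_vars.items()
        }

    def with_burnout(
        self, schema: FeatureSchema, normalized: Mapping[str, float], assessment_point: str
    ) -> "ParticipantProfile":
        """Copy of this profile with updated burnout scores at a new assessment."""
        nums = dict(self.numerical_values)
        for sub, var in schema.burnout_vars.items():
            nums[var] = float(normalized[sub])
        return replace(
            self, numerical_values=nums, assessment_point=assessment_point
        )

    def to_dict(self) -> dict:
        return {
            "participant_id": self.participant_id,
            "assessment_point": self.assessment_point,
            "categorical_values": dict(self.categorical_values),
            "numerical_values": {k: float(v) for k, v in self.numerical_values.items()},
        }

    @classmethod
    def from_dict(cls, d: Mapping[str, Any]) -> "ParticipantProfile":
        return cls(
            participant_id=str(d["participant_id"]),
            categorical_values=dict(d["categorical_values"]),
            numerical_values={k: float(v) for k, v in d["numerical_values"].items()},
            assessment_point=d.get("assessment_point", "pretest"),
        )


@dataclass(frozen=True)
class BurnoutScores:
    """CBI subdimension scores (raw scale) with derived total and normalization.

    ``personal`` and ``client_related`` live on 0–31.5, ``work_related``
    on 0–37; the total is their sum on 0–100.
    """

    personal: float
    work_related: float
    client_related: float

    @property
    def total(self) -> float:
        return self.personal + self.work_related + self.client_related

    @property
    def normalized(self) -> dict[str, float]:
        """Each subdimension rescaled to 0–100 (raw / subdomain max * 100)."""
        return {
            "personal": self.personal / SUBDIM_MAX["personal"] * 100.0,
            "work": self.work_related / SUBDIM_MAX["work"] * 100.0,
            "client": self.client_related / SUBDIM_MAX["client"] * 100.0,
        }

    @classmethod
    def from_normalized(
        cls, personal: float, work: float, client: float
    ) -> "BurnoutScores":
        """Build from normalized 0–100 subdimension scores."""
        return cls(
            personal=personal * SUBDIM_MAX["personal"] / 100.0,
            work_related=work * SUBDIM_MAX["work"] / 100.0,
            client_related=client * SUBDIM_MAX["client"] / 100.0,
        )

    def validate(self) -> None:
        for sub, raw in (
            ("personal", self.personal),
            ("work", self.work_related),
            ("client", self.client_related),
        ):
            if not (0.0 <= raw <= SUBDIM_MAX[sub]):
                raise ValueError(
                    f"{sub} burnout score {raw} outside [0, {SUBDIM_MAX[sub]}]"
                )


def normalize_burnout(raw: BurnoutScores) -> dict[str, float]:
    """Rescale raw CBI subdimension scores to the common 0–100 scale.

    Raises ``ValueError`` if any raw score is outside its subdomain range.
    """
    raw.validate()
    return raw.normalized


@dataclass(frozen=True)
class ProgramOutcome:
    """Pre/post burnout scores and satisfaction for one completed program."""

    program: str
    pre: BurnoutScores
    post: BurnoutScores
    satisfaction: int | None = None

    def __post_init__(self) -> None:
        if self.program not in PROGRAMS:
            raise ValueError(f"unknown program {self.program!r}")
        if self.satisfaction is not None and self.satisfaction not in (1, 2, 3, 4, 5):
            raise ValueError(f"satisfaction must be in 1..5, got {self.satisfaction!r}")


@dataclass(frozen=True)
class ValidRecord:
    """One program stage admitted to the knowledge base.

    ``profile`` is the participant's state at the assessment preceding
    the program; ``reduction`` is the effective subdimension's drop on
    the normalized 0–100 scale (must be >= 5).  ``insertion_index`` is
    assigned by the knowledge base on append.
    """

    profile: ParticipantProfile
    program: str
    effective_subdimension: str
    reduction: float
    insertion_index: int | None = None

    def __post_init__(self) -> None:
        if self.program not in PROGRAMS:
            raise ValueError(f"unknown program {self.program!r}")
        if self.effective_subdimension not in SUBDIMENSIONS:
            raise ValueError(
                f"unknown subdimension {self.effective_subdimension!r}"
            )
        if self.reduction < VALID_REDUCTION_THRESHOLD:
            raise ValueError(
                f"reduction {self.reduction} below validity threshold "
                f"{VALID_REDUCTION_THRESHOLD}"
            )

    def to_dict(self) -> dict:
        return {
            "profile": self.profile.to_dict(),
            "program": self.program,
            "effective_subdimension": self.effective_subdimension,
            "reduction": float(self.reduction),
            "insertion_index": self.insertion_index,
        }

    @classmethod
    def from_dict(cls, d: Mapping[str, Any]) -> "ValidRecord":
        return cls(
            profile=ParticipantProfile.from_dict(d["profile"]),
            program=d["program"],
            effective_subdimension=d["effective_subdimension"],
            reduction=float(d["reduction"]),
            insertion_index=d.get("insertion_index"),
        )


class KnowledgeBase:
    """The ordered, append-only store of valid records the recommender searches.

    Records keep strictly increasing insertion indices; a (participant,
    assessment point) pair may appear at most once, matching the rule
    that each of a participant's two program stages contributes at most
    one valid record.
    """

    def __init__(
        self,
        schema: FeatureSchema,
        records: Iterable[ValidRecord] = (),
    ) -> None:
        self.schema = schema
        self._records: list[ValidRecord] = []
        self._keys: set[tuple[str, str]] = set()
        # per-record feature rows cached for vectorized ranking
        self._cat_rows: list[np.ndarray] = []
        self._num_rows: list[np.ndarray] = []
        for r in records:
            self.append(r)

    # -- container protocol ---------------------------------------------

    def __len__(self) -> int:
        return len(self._records)

    def __iter__(self) -> Iterator[ValidRecord]:
        return iter(self._records)

    def __getitem__(self, i: int) -> ValidRecord:
        return self._records[i]

    @property
    def records(self) -> tuple[ValidRecord, ...]:
        return tuple(self._records)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, KnowledgeBase):
            return NotImplemented
        return self.schema == other.schema and self._records == other._records

    # -- mutation --------------------------------------------------------

    def append(self, record: ValidRecord) -> ValidRecord:
        """Append one valid record, assigning the next insertion index.

        Raises ``ValueError`` on a duplicate (participant, stage) record
        or an insertion index that breaks the append-only order.
        """
        self.schema.validate_profile(record.profile)
        key = (record.profile.participant_id, record.profile.assessment_point)
        if key in self._keys:
            raise ValueError(
                f"duplicate valid record for participant "
                f"{key[0]!r} at {key[1]!r}"
            )
        idx = len(self._records)
        if record.insertion_index is None:
            record = replace(record, insertion_index=idx)
        elif record.insertion_index != idx:
            raise ValueError(
                f"insertion_index {record.insertion_index} breaks append-only "
                f"order (expected {idx})"
            )
        self._records.append(record)
        self._keys.add(key)
        self._cat_rows.append(self._cat_row(record.profile))
        self._num_rows.append(self._num_row(record.profile))
        return record

    def extend(self, records: Iterable[ValidRecord]) -> None:
        for r in records:
            self.append(r)

    # -- vectorized feature access --------------------------------------

    def _cat_row(self, profile: ParticipantProfile) -> np.ndarray:
        return np.array(
            [profile.categorical_values[v.name] for v in self.schema.categorical],
            dtype=object,
        )

    def _num_row(self, profile: ParticipantProfile) -> np.ndarray:
        return np.array(
            [profile.numerical_values[v.name] for v in self.schema.numerical],
            dtype=float,
        )

    def feature_matrices(self) -> tuple[np.ndarray, np.ndarray]:
        """(categorical, numerical) record-by-variable matrices in schema order."""
        n = len(self._records)
        cat = (
            np.stack(self._cat_rows)
            if n
            else np.empty((0, len(self.schema.categorical)), dtype=object)
        )
        num = (
            np.stack(self._num_rows)
            if n
            else np.empty((0, len(self.schema.numerical)), dtype=float)
        )
        return cat, num

    # -- persistence -----------------------------------------------------

    def to_jsonl(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            for r in self._records:
                fh.write(json.dumps(r.to_dict()) + "\n")

    @classmethod
    def from_jsonl(cls, path: str | Path, schema: FeatureSchema) -> "KnowledgeBase":
        kb = cls(schema)
        with open(path) as fh:
            for lineno, line in enumerate(fh, start=1):
                line = line.strip()
                if not line:
                    continue
                try:
                    rec = ValidRecord.from_dict(json.loads(line))
                    kb.append(rec)
                except (ValueError, KeyError, json.JSONDecodeError) as exc:
                    raise ValueError(f"{path}:{lineno}: corrupt record: {exc}") from exc
        return kb


# -- schema loading ------------------------------------------------------


def load_schema(config: Mapping[str, Any] | str | Path) -> FeatureSchema:
    """Build a validated :class:`FeatureSchema` from a config dict or YAML/JSON file.

    The config declares every variable with its kind and codes/range::

        variables:
          - {name: sex, kind: categorical, codes: [1, 2]}
          - {name: age, kind: numerical, min: 22, max: 60}
        stage1_vars: [...]   # optional, defaults to all
        stage2_vars: [...]
    """
    if isinstance(config, (str, Path)):
        with open(config) as fh:
            config = yaml.safe_load(fh)
    if not isinstance(config, Mapping):
        raise SchemaError("schema config must be a mapping")
    variables = config.get("variables", [])
    cats: list[CategoricalVar] = []
    nums: list[NumericalVar] = []
    for spec in variables:
        name = spec.get("name")
        kind = spec.get("kind")
        if not name:
            raise SchemaError(f"variable without a name: {spec!r}")
        if kind == "categorical":
            if "codes" not in spec:
                raise SchemaError(f"categorical variable {name!r} missing codes")
            cats.append(CategoricalVar(name=name, codes=tuple(spec["codes"])))
        elif kind == "numerical":
            if "min" not in spec or "max" not in spec:
                raise SchemaError(f"numerical variable {name!r} missing min/max range")
            nums.append(
                NumericalVar(name=name, vmin=float(spec["min"]), vmax=float(spec["max"]))
            )
        else:
            raise SchemaError(f"variable {name!r} has unknown kind {kind!r}")
    kwargs: dict[str, Any] = {}
    if config.get("stage1_vars"):
        kwargs["stage1_vars"] = tuple(config["stage1_vars"])
    if config.get("stage2_vars"):
        kwargs["stage2_vars"] = tuple(config["stage2_vars"])
    if config.get("burnout_vars"):
        kwargs["burnout_vars"] = dict(config["burnout_vars"])
    return FeatureSchema(categorical=tuple(cats), numerical=tuple(nums), **kwargs)


#: Default schema configuration: 5 categorical + 17 numerical variables.
#: Ranges of the coded demographics are chosen so that the hospital-size
#: (1–5, R=4), clinical-experience (1–6, R=5) and age (22–60, R=38)
#: contributions reproduce the published worked example of the measure.
DEFAULT_SCHEMA_CONFIG: dict[str, Any] = {
    "variables": [
        {"name": "sex", "kind": "categorical", "codes": [1, 2]},
        {"name": "marital_status", "kind": "categorical", "codes": [1, 2, 3]},
        {"name": "position", "kind": "categorical", "codes": [1, 2, 3]},
        {"name": "department", "kind": "categorical", "codes": [1, 2, 3, 4, 5]},
        {"name": "shift_type", "kind": "categorical", "codes": [1, 2, 3, 4]},
        {"name": "age", "kind": "numerical", "min": 22, "max": 60},
        {"name": "hospital_size", "kind": "numerical", "min": 1, "max": 5},
        {"name": "clinical_experience", "kind": "numerical", "min": 1, "max": 6},
        {"name": "overtime", "kind": "numerical", "min": 1, "max": 6},
        {"name": "turnover_intention", "kind": "numerical", "min": 0, "max": 10},
        {"name": "job_stress", "kind": "numerical", "min": 23, "max": 115},
        {"name": "stress_response", "kind": "numerical", "min": 0, "max": 88},
        {"name": "coping_total", "kind": "numerical", "min": 33, "max": 99},
        {"name": "coping_problem_solving", "kind": "numerical", "min": 11, "max": 33},
        {"name": "coping_social_support", "kind": "numerical", "min": 11, "max": 33},
        {"name": "coping_avoidance", "kind": "numerical", "min": 11, "max": 33},
        {"name": "burnout_personal", "kind": "numerical", "min": 0, "max": 100},
        {"name": "burnout_work", "kind": "numerical", "min": 0, "max": 100},
        {"name": "burnout_client", "kind": "numerical", "min": 0, "max": 100},
        {"name": "reserved_1", "kind": "numerical", "min": 0, "max": 100},
        {"name": "reserved_2", "kind": "numerical", "min": 0, "max": 100},
        {"name": "reserved_3", "kind": "numerical", "min": 0, "max": 100},
    ],
    # stage 1 uses everything; stage 2 restricts to demographics / work
    # characteristics plus the burnout subdimensions
    "stage2_vars": [
        "sex",
        "marital_status",
        "position",
        "department",
        "shift_type",
        "age",
        "hospital_size",
        "clinical_experience",
        "overtime",
        "turnover_intention",
        "burnout_personal",
        "burnout_work",
        "burnout_client",
    ],
}


def default_schema() -> FeatureSchema:
    """The shipped default feature schema (5 categorical + 17 numerical)."""
    return load_schema(DEFAULT_SCHEMA_CONFIG)
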