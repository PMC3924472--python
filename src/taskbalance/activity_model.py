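"""Activities, areas and the discrete attribute schema the decision engine splits on.

An *activity* is an everyday task (do homework, walk the dog) described by a
small set of discrete attributes: how urgent its deadline is, who asked for it,
and which life area it belongs to.  The decision engine only ever sees these
discrete attributes, so free-form deadlines are bucketed into five ordered
urgency levels before they reach the tree.
"""

from __future__ import annotations

import datetime as _dt
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

__all__ = [
    "DEADLINE_BUCKETS",
    "DEFAULT_AREAS",
    "Activity",
    "AttributeSchema",
    "SchemaError",
    "Violation",
    "bucket_deadline",
    "default_schema",
    "validate_activity",
]

#: Deadline urgency levels, most urgent first.
DEADLINE_BUCKETS: tuple[str, ...] = ("overdue", "today", "within_week", "later", "none")

#: Life areas shipped by default; the schema is config-driven, so deployments
#: may add or replace areas.
DEFAULT_AREAS: tuple[str, ...] = ("academic", "personal", "family", "leisure")

#: Who asked for the activity, in decreasing precedence for weight ranking.
DEFAULT_REQUESTERS: tuple[str, ...] = ("father", "mother", "someone_else", "nobody")


class SchemaError(ValueError):
    """A schema definition itself is malformed (distinct from a validation failure)."""


@dataclass(frozen=True)
class Violation:
    """One reason an activity fails schema validation."""

    kind: str  # "missing-attribute" | "unknown-attribute" | "unknown-value"
    attribute: str
    value: str | None = None

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        if self.kind == "unknown-value":
            return f"unknown value {self.value!r} for attribute {self.attribute!r}"
        return f"{self.kind.replace('-', ' ')}: {self.attribute!r}"


@dataclass(frozen=True)
class AttributeSchema:
    """Ordered mapping of attribute name -> finite ordered value domain.

    Domains are ordered because the weight-assignment policy ranks leaf paths
    by domain position (e.g. ``overdue`` outranks ``today``).
    """

    attributes: tuple[tuple[str, tuple[str, ...]], ...]

    def __post_init__(self) -> None:
        names = [name for name, _ in self.attributes]
        if len(set(names)) != len(names):
            raise SchemaError("attribute names must be unique")
        for name, domain in self.attributes:
            if not name:
                raise SchemaError("attribute names must be non-empty")
            if len(domain) < 2:
                raise SchemaError(f"domain of {name!r} needs >= 2 values")
            if len(set(domain)) != len(domain):
                raise SchemaError(f"domain of {name!r} has duplicate values")

    @property
    def names(self) -> tuple[str, ...]:
        return tuple(name for name, _ in self.attributes)

    def domain(self, attribute: str) -> tuple[str, ...]:
        for name, domain in self.attributes:
            if name == attribute:
                return domain
        raise KeyError(attribute)

    def __contains__(self, attribute: str) -> bool:
        return attribute in self.names

    def grid(self) -> Iterable[dict[str, str]]:
        """Enumerate every complete assignment over the attribute grid."""
        import itertools

        names = self.names
        domains = [self.domain(n) for n in names]
        for combo in itertools.product(*domains):
            yield dict(zip(names, combo))

    def to_dict(self) -> dict:
        return {"attributes": [[n, list(d)] for n, d in self.attributes]}

    @classmethod
    def from_dict(cls, payload: Mapping) -> "AttributeSchema":
        try:
            attrs = tuple((str(n), tuple(str(v) for v in d)) for n, d in payload["attributes"])
        except (KeyError, TypeError, ValueError) as exc:
            raise SchemaError(f"malformed schema document: {exc}") from exc
        return cls(attrs)

    @classmethod
    def from_json(cls, path: str | Path) -> "AttributeSchema":
        return cls.from_dict(json.loads(Path(path).read_text()))


def default_schema(areas: Sequence[str] = DEFAULT_AREAS) -> AttributeSchema:
    """The minimal schema the tool ships with: deadline urgency, requester, area."""
    return AttributeSchema(
        (
            ("deadline_bucket", DEADLINE_BUCKETS),
            ("requested_by", DEFAULT_REQUESTERS),
            ("area", tuple(areas)),
        )
    )


@dataclass(frozen=True)
class Activity:
    """An everyday task with a complete attribute assignment."""

    id: str
    name: str
    assignment: Mapping[str, str] = field(default_factory=dict)

    @property
    def area(self) -> str | None:
        return self.assignment.get("area")

    def to_dict(self) -> dict:
        return {"id": self.id, "name": self.name, "assignment": dict(self.assignment)}

    @classmethod
    def from_dict(cls, payload: Mapping) -> "Activity":
        return cls(
            id=str(payload["id"]),
            name=str(payload.get("name", payload["id"])),
            assignment={str(k): str(v) for k, v in payload.get("assignment", {}).items()},
        )


def validate_activity(activity: Activity, schema: AttributeSchema) -> list[Violation]:
    """Check an activity against the schema; an empty list means it conforms.

    Returns one :class:`Violation` per missing attribute, unknown attribute,
    or out-of-domain value.  A malformed schema raises :class:`SchemaError`
    instead (that is a configuration bug, not a bad activity).
    """
    if not isinstance(schema, AttributeSchema):
        raise SchemaError("schema must be an AttributeSchema")
    violations: list[Violation] = []
    for name, domain in schema.attributes:
        if name not in activity.assignment:
            violations.append(Violation("missing-attribute", name))
        elif activity.assignment[name] not in domain:
            violations.append(Violation("unknown-value", name, activity.assignment[name]))
    for name in activity.assignment:
        if name not in schema:
            violations.append(Violation("unknown-attribute", name))
    return violations


def bucket_deadline(
    deadline: _dt.date | str | None, reference: _dt.date | str
) -> str:
    """Discretise a calendar deadline into one of the five urgency buckets.

    ``None`` means the activity has no deadline (bucket ``none``); a deadline
    strictly before the reference date is ``overdue``; equal is ``today``;
    within the half-open week (reference, reference + 7 days] is
    ``within_week``; anything further out is ``later``.
    """
    reference = _coerce_date(reference)
    if deadline is None:
        return "none"
    deadline = _coerce_date(deadline)
    if deadline < reference:
        return "overdue"
    if deadline == reference:
        return "today"
    if deadline <= reference + _dt.timedelta(days=7):
        return "within_week"
    return "later"


def _coerce_date(value: _dt.date | str) -> _dt.date:
    if isinstance(value, _dt.datetime):
        return value.date()
    if isinstance(value, _dt.date):
        return value
    try:
        return _dt.date.fromisoformat(str(value))
    except ValueError as exc:
        raise ValueError(f"not an ISO-8601 calendar date: {value!r}") from exc
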