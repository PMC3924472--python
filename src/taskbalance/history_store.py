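"""Supervisor layer: persistent history of queries and quiz answers.

Every comparison a user makes — whether a free query or a graded quiz
question — is kept as one record with its date, so a supervisor can review
sessions, see which life areas a user finds hardest, and inject custom
questions aimed at that user's weak spots.

Persistence is a flat append-only JSON Lines file (one object per line) with
a ``_type`` discriminator separating records from supervisor questions; a CSV
export is provided for spreadsheet review.
"""

from __future__ import annotations

import datetime as _dt
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

from .quiz_engine import QuizQuestion
from .activity_model import Activity, AttributeSchema, validate_activity
from .decision_engine import PriorityDecision

__all__ = [
    "QueryRecord",
    "AreaReport",
    "HistoryStore",
    "append_record",
    "area_report",
    "add_custom_question",
]

_KINDS = ("query", "quiz")


@dataclass(frozen=True)
class QueryRecord:
    """One logged comparison: who, when, which pair, what was decided."""

    user: str
    timestamp: str  # ISO-8601
    kind: str  # "query" | "quiz"
    pair: tuple[str, str]  # activity ids
    winner: str
    rationale: str
    area: str
    correct: bool | None = None  # present iff kind == "quiz"

    def __post_init__(self) -> None:
        if self.kind not in _KINDS:
            raise ValueError(f"kind must be one of {_KINDS}, got {self.kind!r}")
        try:
            _dt.datetime.fromisoformat(self.timestamp)
        except ValueError as exc:
            raise ValueError(f"timestamp {self.timestamp!r} is not ISO-8601") from exc
        if (self.correct is None) == (self.kind == "quiz"):
            raise ValueError("correct flag must be present iff kind is 'quiz'")

    def to_dict(self) -> dict:
        return {
            "user": self.user,
            "timestamp": self.timestamp,
            "kind": self.kind,
            "pair": list(self.pair),
            "winner": self.winner,
            "rationale": self.rationale,
            "area": self.area,
            "correct": self.correct,
        }

    @classmethod
    def from_dict(cls, payload: Mapping) -> "QueryRecord":
        return cls(
            user=str(payload["user"]),
            timestamp=str(payload["timestamp"]),
            kind=str(payload["kind"]),
            pair=(str(payload["pair"][0]), str(payload["pair"][1])),
            winner=str(payload["winner"]),
            rationale=str(payload.get("rationale", "")),
            area=str(payload["area"]),
            correct=payload.get("correct"),
        )

    @classmethod
    def from_decision(
        cls,
        user: str,
        decision: PriorityDecision,
        area: str,
        *,
        kind: str = "query",
        correct: bool | None = None,
        timestamp: _dt.datetime | None = None,
    ) -> "QueryRecord":
        when = timestamp or _dt.datetime.now(_dt.timezone.utc)
        return cls(
            user=user,
            timestamp=when.isoformat(),
            kind=kind,
            pair=(decision.winner, decision.loser),
            winner=decision.winner,
            rationale=decision.rationale,
            area=area,
            correct=correct,
        )


@dataclass(frozen=True)
class AreaReport:
    """Per-area attempt/error counts for one user, with the hardest area.

    ``rates`` maps area -> error rate (0.0 when the area was never
    attempted); ``hardest`` is the attempted area with the maximal error
    rate, ties broken lexicographically, or None with no quiz history.
    """

    attempts: Mapping[str, int]
    errors: Mapping[str, int]
    rates: Mapping[str, float]
    hardest: str | None

    def to_dict(self) -> dict:
        return {
            "attempts": dict(self.attempts),
            "errors": dict(self.errors),
            "error_rates": dict(self.rates),
            "hardest_area": self.hardest,
        }


@dataclass
class HistoryStore:
    """In-memory history with JSON Lines persistence."""

    records: list[QueryRecord] = field(default_factory=list)
    custom_questions: list[QuizQuestion] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.records)

    # -- persistence ------------------------------------------------------

    def save(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            for rec in self.records:
                fh.write(json.dumps({"_type": "record", **rec.to_dict()}) + "\n")
            for q in self.custom_questions:
                fh.write(json.dumps({"_type": "custom_question", **q.to_dict()}) + "\n")

    @classmethod
    def load(cls, path: str | Path) -> "HistoryStore":
        store = cls()
        with open(path) as fh:
            for line in fh:
                line = line.strip()
                if not line:
                    continue
                payload = json.loads(line)
                if payload.pop("_type", "record") == "custom_question":
                    store.custom_questions.append(_question_from_dict(payload))
                else:
                    store.records.append(QueryRecord.from_dict(payload))
        return store

    def export_csv(self, path: str | Path) -> None:
        """Flat CSV of the record log for supervisors."""
        import pandas as pd

        pd.DataFrame([r.to_dict() for r in self.records]).to_csv(path, index=False)


def _question_from_dict(payload: Mapping) -> QuizQuestion:
    from .decision_engine import PriorityDecision

    answer = payload["correct_answer"]
    return QuizQuestion(
        question_id=str(payload["question_id"]),
        pair=(
            Activity.from_dict(payload["pair"][0]),
            Activity.from_dict(payload["pair"][1]),
        ),
        area=str(payload["area"]),
        correct_answer=PriorityDecision(**answer),
        source=str(payload.get("source", "supervisor")),
    )


def append_record(store: HistoryStore, record: QueryRecord) -> HistoryStore:
    """Append one well-formed record, preserving insertion order."""
    if not isinstance(record, QueryRecord):
        raise ValueError("append_record expects a QueryRecord")
    store.records.append(record)
    return store


def area_report(store: HistoryStore, user: str) -> AreaReport:
    """Per-area difficulty over the user's quiz records.

    Query records carry no correctness information and are excluded; an
    unknown user simply yields the empty report.
    """
    attempts: dict[str, int] = {}
    errors: dict[str, int] = {}
    for rec in store.records:
        if rec.user != user or rec.kind != "quiz":
            continue
        attempts[rec.area] = attempts.get(rec.area, 0) + 1
        if not rec.correct:
            errors[rec.area] = errors.get(rec.area, 0) + 1
    rates = {
        area: (errors.get(area, 0) / n if n else 0.0)
        for area, n in attempts.items()
    }
    attempted = [a for a, n in attempts.items() if n > 0]
    hardest = min(attempted, key=lambda a: (-rates[a], a)) if attempted else None
    return AreaReport(attempts, errors, rates, hardest)


def add_custom_question(
    store: HistoryStore, question: QuizQuestion, schema: AttributeSchema
) -> HistoryStore:
    """Register a supervisor-authored question in the quiz bank.

    Both activities must validate against the schema; the stored question is
    marked with supervisor provenance and is graded exactly like a generated
    one.
    """
    for act in question.pair:
        violations = validate_activity(act, schema)
        if violations:
            raise ValueError(
                f"custom question activity {act.id!r} fails validation: "
                + "; ".join(str(v) for v in violations)
            )
    if question.source != "supervisor":
        question = QuizQuestion(
            question.question_id, question.pair, question.area,
            question.correct_answer, source="supervisor",
        )
    store.custom_questions.append(question)
    return store
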