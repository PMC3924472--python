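"""Adaptive pairwise-prioritisation quiz.

The training tool shows the user two fully described activities and asks
which one takes priority; the decision tree holds the correct answer.
Question selection adapts to the user: each life area keeps an
attempt/error count, and areas are sampled with probability proportional to
their Laplace-smoothed error rate ``(errors + alpha) / (attempts + 2*alpha)``,
so the areas that cause the most difficulty come up most often while unseen
areas keep strictly positive probability (cold start needs no special case).
"""

from __future__ import annotations

import datetime as _dt
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np

from .activity_model import Activity, AttributeSchema
from .decision_engine import Node, PriorityDecision, prioritise

__all__ = [
    "DifficultyProfile",
    "QuizQuestion",
    "GradedAnswer",
    "selection_distribution",
    "generate_question",
    "grade_answer",
]


@dataclass(frozen=True)
class DifficultyProfile:
    """Per-area attempt/error counts driving quiz adaptation."""

    attempts: Mapping[str, int] = field(default_factory=dict)
    errors: Mapping[str, int] = field(default_factory=dict)
    alpha: float = 1.0  # Laplace smoothing strength

    def __post_init__(self) -> None:
        if self.alpha <= 0:
            raise ValueError("smoothing alpha must be positive")
        for area, n_err in self.errors.items():
            if n_err < 0 or n_err > self.attempts.get(area, 0):
                raise ValueError(f"errors must satisfy 0 <= errors <= attempts for {area!r}")
        if any(n < 0 for n in self.attempts.values()):
            raise ValueError("attempts must be nonnegative")

    def record(self, area: str, correct: bool) -> "DifficultyProfile":
        """New profile with one more attempt (and error, if wrong) in *area*."""
        attempts = dict(self.attempts)
        errors = dict(self.errors)
        attempts[area] = attempts.get(area, 0) + 1
        if not correct:
            errors[area] = errors.get(area, 0) + 1
        return replace(self, attempts=attempts, errors=errors)

    def to_dict(self) -> dict:
        return {
            "attempts": dict(self.attempts),
            "errors": dict(self.errors),
            "alpha": self.alpha,
        }


@dataclass(frozen=True)
class QuizQuestion:
    """One pairwise question with its engine-computed correct answer."""

    question_id: str
    pair: tuple[Activity, Activity]
    area: str
    correct_answer: PriorityDecision
    source: str = "generated"  # "generated" | "supervisor"

    def to_dict(self) -> dict:
        return {
            "question_id": self.question_id,
            "pair": [a.to_dict() for a in self.pair],
            "area": self.area,
            "correct_answer": self.correct_answer.to_dict(),
            "source": self.source,
        }


@dataclass(frozen=True)
class GradedAnswer:
    question_id: str
    chosen: str
    correct: bool
    timestamp: str  # ISO-8601 UTC

    def to_dict(self) -> dict:
        return {
            "question_id": self.question_id,
            "chosen": self.chosen,
            "correct": self.correct,
            "timestamp": self.timestamp,
        }


def selection_distribution(
    profile: DifficultyProfile, areas: Sequence[str]
) -> dict[str, float]:
    """Area sampling probabilities from smoothed per-area error rates.

    With no history every area scores ``alpha / (2*alpha) = 1/2`` and the
    distribution is uniform; areas with relatively more errors get strictly
    more probability; as ``alpha`` grows the distribution flattens back to
    uniform.
    """
    if not areas:
        raise ValueError("area list must be non-empty")
    a = profile.alpha
    raw = {
        area: (profile.errors.get(area, 0) + a)
        / (profile.attempts.get(area, 0) + 2 * a)
        for area in areas
    }
    total = sum(raw.values())
    return {area: score / total for area, score in raw.items()}


def _as_rng(rng: np.random.Generator | int | None) -> np.random.Generator:
    if isinstance(rng, np.random.Generator):
        return rng
    return np.random.default_rng(rng)


def generate_question(
    bank: Sequence[Activity],
    profile: DifficultyProfile,
    tree: Node,
    schema: AttributeSchema,
    rng: np.random.Generator | int | None = None,
) -> QuizQuestion:
    """Sample an area from the difficulty distribution, then a distinct
    activity pair uniformly within it; the tree supplies the correct answer.

    Only areas holding at least two bank activities are eligible (an area
    needs a pair to pose a question); their probabilities are renormalised.
    Identical seeds reproduce identical questions.
    """
    rng = _as_rng(rng)
    by_area: dict[str, list[Activity]] = {}
    for act in bank:
        if act.area is not None:
            by_area.setdefault(act.area, []).append(act)
    eligible = sorted(a for a, acts in by_area.items() if len(acts) >= 2)
    if not eligible:
        raise ValueError("no area in the bank holds at least two activities")

    dist = selection_distribution(profile, eligible)
    areas = list(dist)
    probs = np.array([dist[a] for a in areas])
    area = areas[rng.choice(len(areas), p=probs / probs.sum())]

    pool = sorted(by_area[area], key=lambda act: act.id)
    i, j = rng.choice(len(pool), size=2, replace=False)
    first, second = pool[i], pool[j]
    answer = prioritise(tree, first, second, schema)
    qid = f"q-{area}-{first.id}-vs-{second.id}"
    return QuizQuestion(qid, (first, second), area, answer)


def next_question(
    bank: Sequence[Activity],
    profile: DifficultyProfile,
    tree: Node,
    schema: AttributeSchema,
    rng: np.random.Generator | int | None = None,
    pending: Sequence[QuizQuestion] = (),
    served_ids: set[str] | None = None,
) -> QuizQuestion:
    """Next quiz question: pending supervisor questions first, then generated.

    *pending* is typically the history store's supervisor question list;
    *served_ids* (mutated when given) tracks which of them were already
    posed, so each is served once per session.
    """
    for question in pending:
        if served_ids is None or question.question_id not in served_ids:
            if served_ids is not None:
                served_ids.add(question.question_id)
            return question
    return generate_question(bank, profile, tree, schema, rng)


def grade_answer(
    question: QuizQuestion,
    chosen_id: str,
    profile: DifficultyProfile,
    *,
    timestamp: _dt.datetime | None = None,
) -> tuple[GradedAnswer, DifficultyProfile]:
    """Grade one answer and return the updated difficulty profile.

    The input profile is never modified; the question's area gets one more
    attempt and, on a wrong answer, one more error.
    """
    pair_ids = {question.pair[0].id, question.pair[1].id}
    if chosen_id not in pair_ids:
        raise ValueError(f"chosen id {chosen_id!r} is not in the question pair {sorted(pair_ids)}")
    correct = chosen_id == question.correct_answer.winner
    when = timestamp or _dt.datetime.now(_dt.timezone.utc)
    graded = GradedAnswer(
        question.question_id, chosen_id, correct, when.isoformat()
    )
    return graded, profile.record(question.area, correct)
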