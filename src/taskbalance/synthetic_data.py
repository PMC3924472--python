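"""Synthetic fixtures: labeled tables, quiz sessions and Likert cohorts.

No raw study data was ever deposited, so every consumer module is exercised
against generated stand-ins:

* labeled example tables drawn from a known ground-truth tree (optionally
  label-flipped at a configurable noise rate) for induction round-trips;
* quiz sessions from simulated users with per-area competence, for the
  adaptation and reporting layers;
* Likert response cohorts calibrated so their *scored* group statistics
  reproduce printed group means (SUS on its 2.5-point grid, TMBQ per-factor
  means), for the questionnaire layer.

SUS calibration works in score space: a group target mean is converted to an
integer raw-point total (each respondent contributes 0-40 raw points, 2.5
score points each), the total is spread over respondents, optionally
hill-climbed toward a target standard deviation, and each raw score is then
inverted to a 10-item response vector.  Every generator is a pure function of
its spec and seed.
"""

from __future__ import annotations

import datetime as _dt
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .activity_model import Activity, AttributeSchema
from .decision_engine import LABELS, LabeledExample, Node, classify
from .history_store import QueryRecord
from .questionnaires import (
    FACTORS,
    FactorMapping,
    SUS_N_ITEMS,
    TMBQ_N_ITEMS,
)
from .quiz_engine import DifficultyProfile, generate_question, grade_answer

__all__ = [
    "UserProfile",
    "CohortSpec",
    "GroupSpec",
    "FeasibilityError",
    "DEFAULT_SUS_COHORT",
    "DEFAULT_TMBQ_COHORT",
    "gen_labeled_examples",
    "gen_quiz_session",
    "gen_sus_cohort",
    "gen_tmbq_cohort",
]


class FeasibilityError(ValueError):
    """A cohort target cannot be attained on the instrument's scale."""


@dataclass(frozen=True)
class UserProfile:
    """Simulated user: per-area probability of answering correctly."""

    user: str
    accuracy: Mapping[str, float]
    default_accuracy: float = 0.5

    def __post_init__(self) -> None:
        for area, p in self.accuracy.items():
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"accuracy for {area!r} must be in [0, 1], got {p}")
        if not 0.0 <= self.default_accuracy <= 1.0:
            raise ValueError("default accuracy must be in [0, 1]")

    def p_correct(self, area: str) -> float:
        return self.accuracy.get(area, self.default_accuracy)


@dataclass(frozen=True)
class GroupSpec:
    label: str
    n: int
    mean: float
    sd: float | None = None

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ValueError("group size must be >= 1")


@dataclass(frozen=True)
class CohortSpec:
    groups: tuple[GroupSpec, ...]
    instrument: str  # "SUS" | "TMBQ"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.instrument not in ("SUS", "TMBQ"):
            raise ValueError("instrument must be 'SUS' or 'TMBQ'")


#: Study-condition cohort: 16 respondents split 7 (younger) / 9 (older),
#: group means 73.93 and 82.5 — pooling to 78.75 exactly.
DEFAULT_SUS_COHORT = CohortSpec(
    groups=(
        GroupSpec("under_15", 7, 73.93, 4.97),
        GroupSpec("over_16", 9, 82.5, 4.68),
    ),
    instrument="SUS",
)

#: Per-factor target means per age group.  F1/F2 are the printed per-group
#: extremes; F3/F4 are not printed and default to values interpolated inside
#: each group's printed range.
DEFAULT_TMBQ_TARGETS: dict[str, dict[str, float]] = {
    "under_15": {"F1": 2.98, "F2": 1.92, "F3": 2.5, "F4": 2.7},
    "over_16": {"F1": 3.44, "F2": 2.30, "F3": 2.8, "F4": 3.1},
}

DEFAULT_TMBQ_COHORT = CohortSpec(
    groups=(GroupSpec("under_15", 8, 0.0), GroupSpec("over_16", 9, 0.0)),
    instrument="TMBQ",
)


# ---------------------------------------------------------------------------
# labeled tables


def gen_labeled_examples(
    truth_tree: Node,
    schema: AttributeSchema,
    n: int,
    noise_rate: float = 0.0,
    seed: int | np.random.Generator = 0,
) -> list[LabeledExample]:
    """Sample labeled examples whose clean labels come from *truth_tree*.

    Assignments are drawn uniformly over the attribute grid; each label is
    flipped independently with probability *noise_rate*.
    """
    if not 0.0 <= noise_rate <= 1.0:
        raise ValueError(f"noise_rate must be in [0, 1], got {noise_rate}")
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    names = schema.names
    domains = [schema.domain(name) for name in names]
    flip = {LABELS[0]: LABELS[1], LABELS[1]: LABELS[0]}
    out: list[LabeledExample] = []
    for _ in range(n):
        assignment = {
            name: domain[rng.integers(len(domain))]
            for name, domain in zip(names, domains)
        }
        label = classify(truth_tree, assignment).label
        if rng.random() < noise_rate:
            label = flip[label]
        out.append(LabeledExample(assignment, label))
    return out


# ---------------------------------------------------------------------------
# quiz sessions


def gen_quiz_session(
    profile: UserProfile,
    n_questions: int,
    bank: Sequence[Activity],
    tree: Node,
    schema: AttributeSchema,
    seed: int | np.random.Generator = 0,
    start: _dt.datetime | None = None,
) -> list[QueryRecord]:
    """Simulate a quiz session for one user with per-area competence.

    Questions come from the adaptive quiz engine (the simulated user's
    running difficulty profile feeds back into selection); each answer is
    correct with the profile's per-area probability.  Records carry
    synthetic timestamps one minute apart.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    when = start or _dt.datetime(2013, 7, 1, 10, 0, tzinfo=_dt.timezone.utc)
    difficulty = DifficultyProfile()
    records: list[QueryRecord] = []
    for i in range(n_questions):
        question = generate_question(bank, difficulty, tree, schema, rng)
        answers_correctly = rng.random() < profile.p_correct(question.area)
        chosen = (
            question.correct_answer.winner
            if answers_correctly
            else question.correct_answer.loser
        )
        graded, difficulty = grade_answer(
            question, chosen, difficulty, timestamp=when + _dt.timedelta(minutes=i)
        )
        records.append(
            QueryRecord(
                user=profile.user,
                timestamp=graded.timestamp,
                kind="quiz",
                pair=(question.pair[0].id, question.pair[1].id),
                winner=question.correct_answer.winner,
                rationale=question.correct_answer.rationale,
                area=question.area,
                correct=graded.correct,
            )
        )
    return records


# ---------------------------------------------------------------------------
# SUS cohorts


def _sus_group_raw_total(spec: GroupSpec) -> int:
    """Integer raw-point total (0-40 per respondent) matching the target mean.

    Raises :class:`FeasibilityError` when no total on the 2.5-point grid
    reproduces the target to two decimals.
    """
    raw_total = round(spec.n * spec.mean / 2.5)
    if not 0 <= raw_total <= 40 * spec.n:
        raise FeasibilityError(
            f"group {spec.label!r}: mean {spec.mean} is outside the 0-100 scale"
        )
    achieved = 2.5 * raw_total / spec.n
    if abs(achieved - spec.mean) > 0.005 + 1e-12:
        raise FeasibilityError(
            f"group {spec.label!r}: no multiple of 2.5 gives mean {spec.mean} "
            f"for n={spec.n} (closest attainable: {achieved:.4f})"
        )
    return raw_total


def _spread_raw_scores(
    total: int, n: int, target_sd: float | None, rng: np.random.Generator
) -> list[int]:
    """Integer raw scores in [0, 40] with the exact given total.

    When a target standard deviation (in raw-point units) is given, random
    unit transfers between pairs of respondents are proposed and accepted
    whenever they move the sample sum of squares toward the target; the total
    is invariant under transfers, so the group mean stays exact.  A unit
    transfer changes the sum of squares by ``2 (s_i - s_j) + 2``, so the
    search granularity is fine and the achieved sd typically lands within
    ~0.1 raw points (0.25 score points) of the target.
    """
    base, rem = divmod(total, n)
    scores = np.array([base + 1] * rem + [base] * (n - rem), dtype=int)
    rng.shuffle(scores)
    if target_sd is not None and n >= 2:
        target_ss = target_sd**2 * (n - 1)
        mean = total / n
        ss = float(((scores - mean) ** 2).sum())
        for _ in range(800 * n):
            if abs(np.sqrt(ss / (n - 1)) - target_sd) <= 0.05:
                break
            i, j = rng.integers(n, size=2)
            if i == j or scores[j] <= 0 or scores[i] >= 40:
                continue
            new_ss = ss + 2.0 * (scores[i] - scores[j]) + 2.0  # move 1 point j -> i
            if abs(new_ss - target_ss) < abs(ss - target_ss):
                scores[i] += 1
                scores[j] -= 1
                ss = new_ss
    return [int(s) for s in scores]


def _raw_score_to_items(raw: int, rng: np.random.Generator) -> list[int]:
    """Invert a raw score (0-40) to a 10-item response vector.

    The raw points are spread over the ten per-item contributions (each 0-4),
    with the remainder placed at seeded-random positions; odd positions then
    decode as ``contribution + 1`` and even positions as ``5 - contribution``
    per the alternating item polarity.
    """
    base, rem = divmod(raw, SUS_N_ITEMS)
    contributions = np.full(SUS_N_ITEMS, base, dtype=int)
    if rem:
        bump = rng.choice(SUS_N_ITEMS, size=rem, replace=False)
        contributions[bump] += 1
    items = [
        int(c + 1) if position % 2 == 1 else int(5 - c)
        for position, c in enumerate(contributions, start=1)
    ]
    return items


def gen_sus_cohort(spec: CohortSpec) -> list[tuple[str, list[int]]]:
    """Generate (group label, 10-item SUS response) pairs matching the spec.

    Each group's scored responses have mean equal to the target to two
    decimals (exactly, on the 2.5-point grid) and, when a target sd is given,
    a sample sd hill-climbed toward it.  Deterministic under the spec's seed.
    """
    if spec.instrument != "SUS":
        raise ValueError("gen_sus_cohort needs a SUS CohortSpec")
    rng = np.random.default_rng(spec.seed)
    out: list[tuple[str, list[int]]] = []
    for group in spec.groups:
        total = _sus_group_raw_total(group)
        raw_sd = group.sd / 2.5 if group.sd is not None else None  # score -> raw units
        raws = _spread_raw_scores(total, group.n, raw_sd, rng)
        for raw in raws:
            out.append((group.label, _raw_score_to_items(raw, rng)))
    return out


# ---------------------------------------------------------------------------
# TMBQ cohorts


def gen_tmbq_cohort(
    spec: CohortSpec,
    mapping: FactorMapping,
    targets: Mapping[str, Mapping[str, float]] | None = None,
) -> list[tuple[str, list[int]]]:
    """Generate (group label, 34-item TMBQ response) pairs.

    *targets* maps group label -> factor -> target mean on the 1-5 scale
    (defaults to the shipped study-condition targets).  Within each group and
    factor, integer item values are chosen so the factor's cohort mean lands
    within rounding of the target, then jittered by sum-preserving unit
    swaps; factor means of the generated cohort match targets within 0.05.
    """
    if spec.instrument != "TMBQ":
        raise ValueError("gen_tmbq_cohort needs a TMBQ CohortSpec")
    targets = targets if targets is not None else DEFAULT_TMBQ_TARGETS
    rng = np.random.default_rng(spec.seed)
    out: list[tuple[str, list[int]]] = []
    for group in spec.groups:
        group_targets = targets[group.label]
        rows = np.ones((group.n, TMBQ_N_ITEMS), dtype=int)
        for factor in FACTORS:
            m = float(group_targets[factor])
            if not 1.0 <= m <= 5.0:
                raise FeasibilityError(
                    f"group {group.label!r}: factor {factor} target {m} outside [1, 5]"
                )
            item_indices = mapping.items_of(factor)
            cells = group.n * len(item_indices)
            total = round(m * cells)
            total = min(max(total, cells), 5 * cells)
            values = _fill_cells(total, cells, rng)
            k = 0
            for r in range(group.n):
                for idx in item_indices:
                    rows[r, idx - 1] = values[k]
                    k += 1
        for r in range(group.n):
            out.append((group.label, [int(v) for v in rows[r]]))
    return out


def _fill_cells(total: int, cells: int, rng: np.random.Generator) -> np.ndarray:
    """Integer Likert values (1-5) with the exact given total, lightly jittered."""
    base, rem = divmod(total, cells)
    values = np.full(cells, base, dtype=int)
    if rem:
        bump = rng.choice(cells, size=rem, replace=False)
        values[bump] += 1
    # sum-preserving unit swaps for within-factor variety
    for _ in range(cells):
        i, j = rng.integers(cells, size=2)
        if i != j and values[i] < 5 and values[j] > 1:
            values[i] += 1
            values[j] -= 1
    rng.shuffle(values)
    return values
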