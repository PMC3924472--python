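"""Scoring for the two evaluation instruments: SUS and the TMBQ.

SUS (System Usability Scale): 10 Likert items (1-5) with alternating
polarity.  Odd-numbered items contribute ``value - 1``, even-numbered items
contribute ``5 - value``; the sum of contributions is multiplied by 2.5,
giving a score on a 2.5-spaced grid from 0 to 100.

TMBQ (Time Management Behavior Questionnaire): 34 Likert items (1-5)
partitioned into four factors — goal/priority setting (F1), time-management
mechanics (F2), preference for disorganisation (F3) and perceived control of
time (F4).  Each factor is scored as the plain mean of its items on the 1-5
scale; no items are reverse-coded.

Group summaries use the sample (n-1) standard deviation, and pooled
statistics are formed from subgroup (n, mean, sd) triples by the
sum-of-squares identity, so printed subgroup statistics can be pooled without
raw scores.  Group comparison uses the Mann-Whitney U test.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
from scipy import stats

__all__ = [
    "FACTORS",
    "FactorMapping",
    "GroupSummary",
    "default_factor_mapping",
    "score_sus",
    "score_tmbq",
    "summarise",
    "cohort_summary",
    "pool_summaries",
    "mann_whitney_u",
]

FACTORS = ("F1", "F2", "F3", "F4")

SUS_N_ITEMS = 10
TMBQ_N_ITEMS = 34


def _check_likert(items: Sequence[int], expected_length: int, instrument: str) -> list[int]:
    values = list(items)
    if len(values) != expected_length:
        raise ValueError(
            f"{instrument} requires exactly {expected_length} items, got {len(values)}"
        )
    for i, v in enumerate(values, start=1):
        if not float(v).is_integer() or not 1 <= int(v) <= 5:
            raise ValueError(
                f"{instrument} item {i} must be an integer in 1..5, got {v!r}"
            )
    return [int(v) for v in values]


def score_sus(items: Sequence[int]) -> float:
    """Overall SUS score in [0, 100] for one 10-item response.

    >>> score_sus((5, 1, 5, 1, 5, 1, 5, 1, 5, 1))
    100.0
    """
    values = _check_likert(items, SUS_N_ITEMS, "SUS")
    contributions = [
        (v - 1) if position % 2 == 1 else (5 - v)
        for position, v in enumerate(values, start=1)
    ]
    return 2.5 * sum(contributions)


@dataclass(frozen=True)
class FactorMapping:
    """Total partition of TMBQ item indices 1..34 into the four factors."""

    assignment: Mapping[int, str]

    def __post_init__(self) -> None:
        indices = set(self.assignment)
        if indices != set(range(1, TMBQ_N_ITEMS + 1)):
            missing = sorted(set(range(1, TMBQ_N_ITEMS + 1)) - indices)
            extra = sorted(indices - set(range(1, TMBQ_N_ITEMS + 1)))
            raise ValueError(
                f"factor mapping must cover items 1..{TMBQ_N_ITEMS} exactly once"
                f" (missing {missing}, extra {extra})"
            )
        factors = set(self.assignment.values())
        if factors != set(FACTORS):
            raise ValueError(f"mapping must use every factor of {FACTORS}, got {sorted(factors)}")

    def items_of(self, factor: str) -> list[int]:
        return sorted(i for i, f in self.assignment.items() if f == factor)

    def to_dict(self) -> dict:
        return {str(i): f for i, f in sorted(self.assignment.items())}

    @classmethod
    def from_dict(cls, payload: Mapping) -> "FactorMapping":
        return cls({int(k): str(v) for k, v in payload.items()})

    @classmethod
    def from_json(cls, path: str | Path) -> "FactorMapping":
        return cls.from_dict(json.loads(Path(path).read_text()))


def default_factor_mapping() -> FactorMapping:
    """The shipped example item split (F1: 10, F2: 11, F3: 8, F4: 5 items).

    The validated Spanish item-to-factor assignment is not public, so this
    mapping is a synthetic placeholder kept as editable configuration; every
    scoring function accepts any valid partition.
    """
    from importlib import resources

    payload = json.loads(
        resources.files("taskbalance").joinpath("data/tmbq_mapping.json").read_text()
    )
    return FactorMapping.from_dict(payload)


def score_tmbq(items: Sequence[int], mapping: FactorMapping) -> dict[str, float]:
    """Per-factor mean scores (1-5 scale) for one 34-item response."""
    if not isinstance(mapping, FactorMapping):
        mapping = FactorMapping(mapping)
    values = _check_likert(items, TMBQ_N_ITEMS, "TMBQ")
    return {
        factor: float(np.mean([values[i - 1] for i in mapping.items_of(factor)]))
        for factor in FACTORS
    }


# ---------------------------------------------------------------------------
# group statistics


@dataclass(frozen=True)
class GroupSummary:
    """Sample size, mean and sample (n-1) standard deviation of one group."""

    n: int
    mean: float
    sd: float | None  # None when n < 2

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ValueError("a group needs n >= 1")
        if self.sd is not None and self.sd < 0:
            raise ValueError("sd must be nonnegative")

    def to_dict(self) -> dict:
        return {"n": self.n, "mean": self.mean, "sd": self.sd}


def summarise(scores: Sequence[float]) -> GroupSummary:
    """Mean and sample sd of raw scores."""
    arr = np.asarray(list(scores), dtype=float)
    if arr.size == 0:
        raise ValueError("cannot summarise an empty score list")
    sd = float(np.std(arr, ddof=1)) if arr.size >= 2 else None
    return GroupSummary(int(arr.size), float(np.mean(arr)), sd)


def pool_summaries(groups: Sequence[GroupSummary]) -> GroupSummary:
    """Combine subgroup (n, mean, sd) triples into the pooled summary.

    Uses the sum-of-squares identity: the pooled corrected sum of squares is
    the within-group part, sum (n_g - 1) sd_g^2, plus the between-group part,
    sum n_g (mean_g - pooled_mean)^2, divided by total n - 1.  This is exactly
    what summarising the concatenated raw scores would give, so printed group
    statistics can be pooled without the raw data.
    """
    if not groups:
        raise ValueError("cannot pool an empty group list")
    total_n = sum(g.n for g in groups)
    pooled_mean = sum(g.n * g.mean for g in groups) / total_n
    if total_n < 2:
        return GroupSummary(total_n, pooled_mean, None)
    ss = 0.0
    for g in groups:
        if g.n >= 2:
            if g.sd is None:
                raise ValueError("sd required for every subgroup with n >= 2")
            ss += (g.n - 1) * g.sd**2
        ss += g.n * (g.mean - pooled_mean) ** 2
    return GroupSummary(total_n, pooled_mean, math.sqrt(ss / (total_n - 1)))


def cohort_summary(
    scores: Sequence[float], group_labels: Sequence[str]
) -> tuple[dict[str, GroupSummary], GroupSummary]:
    """Per-group summaries plus the pooled summary over all scores.

    The pooled summary is computed by combining the per-group statistics with
    :func:`pool_summaries`; by the sum-of-squares identity it equals the
    direct summary of the concatenated scores.
    """
    scores = list(scores)
    group_labels = list(group_labels)
    if len(scores) != len(group_labels):
        raise ValueError("scores and group labels must align")
    if not scores:
        raise ValueError("cannot summarise an empty cohort")
    per_group: dict[str, GroupSummary] = {}
    for label in dict.fromkeys(group_labels):  # first-seen order
        per_group[label] = summarise(
            [s for s, g in zip(scores, group_labels) if g == label]
        )
    pooled = pool_summaries(list(per_group.values()))
    return per_group, pooled


# ---------------------------------------------------------------------------
# group comparison


def mann_whitney_u(
    group_a: Sequence[float], group_b: Sequence[float]
) -> tuple[float, float]:
    """Mann-Whitney U statistic for group A and the two-sided p-value.

    Ranks use midranks for ties.  The p-value is exact (enumeration over all
    label assignments) when the combined sample is small (n_a + n_b <= 12) and
    tie-free; otherwise the normal approximation with tie correction and
    continuity correction is used.  The returned U satisfies
    ``U_a + U_b = n_a * n_b``.
    """
    a = np.asarray(list(group_a), dtype=float)
    b = np.asarray(list(group_b), dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be non-empty")
    combined = np.concatenate([a, b])
    has_ties = np.unique(combined).size < combined.size
    method = "exact" if (a.size + b.size <= 12 and not has_ties) else "asymptotic"
    result = stats.mannwhitneyu(
        a, b, alternative="two-sided", method=method, use_continuity=True
    )
    return float(result.statistic), float(min(result.pvalue, 1.0))
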