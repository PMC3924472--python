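"""ID3 decision-tree induction with per-leaf priority weights.

The tree decides whether a single activity *is a priority* or not from its
discrete attributes.  Every leaf additionally carries a unique positive
integer weight; when two activities fall in the same label class the one whose
leaf has the greater weight wins, so a pairwise comparison always produces an
answer.

Induction is plain ID3: at each node the attribute with maximal information
gain (Shannon entropy, base-2) is chosen greedily, recursing until the label
set is pure, the attributes are exhausted (majority label), or a branch is
empty (parent majority).  There is no pruning and no continuous-attribute
handling — attribute domains are small and finite by construction.
"""

from __future__ import annotations

import json
import math
from collections import Counter
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Callable, Iterable, Mapping, Sequence

from .activity_model import (
    DEADLINE_BUCKETS,
    DEFAULT_REQUESTERS,
    Activity,
    AttributeSchema,
    validate_activity,
)

__all__ = [
    "LABELS",
    "LabeledExample",
    "Leaf",
    "Split",
    "PriorityDecision",
    "entropy",
    "information_gain",
    "induce_tree",
    "assign_weights",
    "classify",
    "prioritise",
    "tree_to_dict",
    "tree_from_dict",
    "save_tree",
    "load_tree",
    "iter_leaves",
    "examples_from_csv",
    "examples_to_csv",
]

PRIORITY = "priority"
NON_PRIORITY = "non_priority"
LABELS = (PRIORITY, NON_PRIORITY)


@dataclass(frozen=True)
class LabeledExample:
    """A complete attribute assignment with its binary priority label."""

    assignment: Mapping[str, str]
    label: str

    def __post_init__(self) -> None:
        if self.label not in LABELS:
            raise ValueError(f"label must be one of {LABELS}, got {self.label!r}")


@dataclass(frozen=True)
class Leaf:
    label: str
    weight: int | None = None
    path: tuple[tuple[str, str], ...] = ()


@dataclass(frozen=True)
class Split:
    attribute: str
    children: Mapping[str, "Node"]
    #: child value holding the training majority; unseen attribute values at
    #: classification time are routed here so a query never dead-ends.
    default_value: str = ""


Node = Leaf | Split


@dataclass(frozen=True)
class PriorityDecision:
    """Outcome of comparing two activities: who wins and why."""

    winner: str
    loser: str
    winner_label: str
    winner_weight: int
    loser_label: str
    loser_weight: int
    tie_break_used: bool
    rationale: str

    def to_dict(self) -> dict:
        return {
            "winner": self.winner,
            "loser": self.loser,
            "winner_label": self.winner_label,
            "winner_weight": self.winner_weight,
            "loser_label": self.loser_label,
            "loser_weight": self.loser_weight,
            "tie_break_used": self.tie_break_used,
            "rationale": self.rationale,
        }


# ---------------------------------------------------------------------------
# entropy / information gain


def entropy(counts: Mapping[str, int]) -> float:
    """Shannon entropy in bits of a label count distribution.

    ``entropy({priority: 4, non_priority: 4}) == 1.0``; a pure set has
    entropy 0.  Labels with zero count contribute nothing.
    """
    total = sum(counts.values())
    if total <= 0:
        raise ValueError("entropy needs at least one positive count")
    if any(c < 0 for c in counts.values()):
        raise ValueError("counts must be nonnegative")
    h = 0.0
    for c in counts.values():
        if c > 0:
            p = c / total
            h -= p * math.log2(p)
    return h


def _label_counts(examples: Sequence[LabeledExample]) -> Counter:
    return Counter(ex.label for ex in examples)


def information_gain(examples: Sequence[LabeledExample], attribute: str) -> float:
    """Entropy reduction achieved by partitioning the examples on *attribute*."""
    if not examples:
        raise ValueError("information_gain needs a non-empty example set")
    if attribute not in examples[0].assignment:
        raise KeyError(f"unknown attribute {attribute!r}")
    total = len(examples)
    by_value: dict[str, list[LabeledExample]] = {}
    for ex in examples:
        by_value.setdefault(ex.assignment[attribute], []).append(ex)
    remainder = sum(
        len(subset) / total * entropy(_label_counts(subset))
        for subset in by_value.values()
    )
    gain = entropy(_label_counts(examples)) - remainder
    return max(gain, 0.0)  # clamp -0.0 / tiny negatives from float round-off


# ---------------------------------------------------------------------------
# induction


def _majority_label(counts: Counter) -> str:
    """Majority label; exact ties resolve toward ``priority`` (conservative:
    when the data cannot decide, treat the activity as a priority)."""
    if counts.get(PRIORITY, 0) >= counts.get(NON_PRIORITY, 0):
        return PRIORITY
    return NON_PRIORITY


def induce_tree(
    examples: Sequence[LabeledExample],
    schema: AttributeSchema,
    *,
    attributes: Sequence[str] | None = None,
) -> Node:
    """Grow an ID3 tree from labeled examples.

    Gain ties between attributes are broken by lexicographic attribute name so
    builds are deterministic.  On consistent examples the tree reproduces every
    training label.  The returned tree has no weights yet; see
    :func:`assign_weights`.
    """
    if not examples:
        raise ValueError("cannot induce a tree from an empty example set")
    attrs = list(attributes if attributes is not None else schema.names)
    return _grow(list(examples), schema, attrs, parent_majority=None, path=())


def _grow(
    examples: list[LabeledExample],
    schema: AttributeSchema,
    attributes: list[str],
    parent_majority: str | None,
    path: tuple[tuple[str, str], ...],
) -> Node:
    if not examples:
        # empty branch: inherit the parent's majority label
        return Leaf(parent_majority or PRIORITY, path=path)
    counts = _label_counts(examples)
    if len(counts) == 1:
        return Leaf(next(iter(counts)), path=path)
    if not attributes:
        return Leaf(_majority_label(counts), path=path)

    best = min(attributes, key=lambda a: (-information_gain(examples, a), a))
    majority = _majority_label(counts)
    remaining = [a for a in attributes if a != best]
    children: dict[str, Node] = {}
    branch_sizes: dict[str, int] = {}
    for value in schema.domain(best):
        subset = [ex for ex in examples if ex.assignment[best] == value]
        branch_sizes[value] = len(subset)
        children[value] = _grow(
            subset, schema, remaining, majority, path + ((best, value),)
        )
    default_value = min(branch_sizes, key=lambda v: (-branch_sizes[v], v))
    return Split(best, children, default_value)


# ---------------------------------------------------------------------------
# weights


def _rank_in(ordering: Sequence[str], value: str | None) -> int:
    """Position of value in an urgency/precedence ordering; absent or unknown
    values rank after every listed one."""
    if value is not None and value in ordering:
        return ordering.index(value)
    return len(ordering)


def default_weight_policy(leaf: Leaf) -> tuple:
    """Ranking key for the shipped weight policy (lower key = heavier weight).

    Priority leaves come first, then more urgent deadline buckets along the
    leaf's path, then requester precedence, then the lexicographic path as the
    final deterministic tie-break.
    """
    path = dict(leaf.path)
    return (
        0 if leaf.label == PRIORITY else 1,
        _rank_in(DEADLINE_BUCKETS, path.get("deadline_bucket")),
        _rank_in(DEFAULT_REQUESTERS, path.get("requested_by")),
        leaf.path,
    )


def iter_leaves(tree: Node) -> Iterable[Leaf]:
    if isinstance(tree, Leaf):
        yield tree
    else:
        for value in tree.children:
            yield from iter_leaves(tree.children[value])


def assign_weights(
    tree: Node, policy: Callable[[Leaf], tuple] = default_weight_policy
) -> Node:
    """Attach a distinct positive integer weight to every leaf.

    Leaves are ranked by *policy* and weights assigned in strictly decreasing
    order from the number of leaves down to 1, so the weights are always a
    permutation of ``1..n_leaves``.
    """
    leaves = sorted(iter_leaves(tree), key=policy)
    weight_of_path = {
        leaf.path: len(leaves) - i for i, leaf in enumerate(leaves)
    }
    return _with_weights(tree, weight_of_path)


def _with_weights(node: Node, weight_of_path: Mapping[tuple, int]) -> Node:
    if isinstance(node, Leaf):
        return replace(node, weight=weight_of_path[node.path])
    return Split(
        node.attribute,
        {v: _with_weights(c, weight_of_path) for v, c in node.children.items()},
        node.default_value,
    )


# ---------------------------------------------------------------------------
# classification / prioritisation


@dataclass(frozen=True)
class Classification:
    label: str
    weight: int | None
    path: tuple[tuple[str, str], ...]
    fallback_used: bool = False


def classify(tree: Node, activity: Activity | Mapping[str, str]) -> Classification:
    """Walk the tree from the root to a leaf for one activity.

    An attribute value missing from a split's children (possible only when the
    schema drifted after induction) is routed to the branch that held the
    training majority, and the result is flagged ``fallback_used``.
    """
    assignment = (
        activity.assignment if isinstance(activity, Activity) else activity
    )
    node = tree
    fallback = False
    while isinstance(node, Split):
        value = assignment.get(node.attribute)
        if value in node.children:
            node = node.children[value]
        else:
            fallback = True
            node = node.children[node.default_value]
    return Classification(node.label, node.weight, node.path, fallback)


def prioritise(tree: Node, a: Activity, b: Activity, schema: AttributeSchema) -> PriorityDecision:
    """Decide which of two activities takes priority.

    Exactly one labelled priority -> it wins outright.  Both priority (or both
    non-priority) -> the greater leaf weight wins and ``tie_break_used`` is
    set.  Identical leaves -> the lexicographically smaller id wins, flagged.
    """
    for act in (a, b):
        violations = validate_activity(act, schema)
        if violations:
            raise ValueError(
                f"activity {act.id!r} fails validation: "
                + "; ".join(str(v) for v in violations)
            )
    ca, cb = classify(tree, a), classify(tree, b)
    if ca.label != cb.label:
        win, lose = (a, b) if ca.label == PRIORITY else (b, a)
        cw = ca if ca.label == PRIORITY else cb
        cl = cb if ca.label == PRIORITY else ca
        return PriorityDecision(
            win.id, lose.id, cw.label, cw.weight, cl.label, cl.weight,
            tie_break_used=False,
            rationale=f"{win.id!r} is labelled priority, {lose.id!r} is not",
        )
    if ca.weight != cb.weight:
        win, lose = (a, b) if ca.weight > cb.weight else (b, a)
        cw, cl = (ca, cb) if ca.weight > cb.weight else (cb, ca)
        return PriorityDecision(
            win.id, lose.id, cw.label, cw.weight, cl.label, cl.weight,
            tie_break_used=True,
            rationale=(
                f"both labelled {ca.label}; {win.id!r} has the greater leaf "
                f"weight ({cw.weight} > {cl.weight})"
            ),
        )
    win, lose = (a, b) if a.id <= b.id else (b, a)
    return PriorityDecision(
        win.id, lose.id, ca.label, ca.weight, cb.label, cb.weight,
        tie_break_used=True,
        rationale=(
            f"identical leaf (label {ca.label}, weight {ca.weight}); "
            f"lexicographically smaller id wins"
        ),
    )


# ---------------------------------------------------------------------------
# serialisation


def tree_to_dict(node: Node) -> dict:
    if isinstance(node, Leaf):
        return {
            "kind": "leaf",
            "label": node.label,
            "weight": node.weight,
            "path": [list(p) for p in node.path],
        }
    return {
        "kind": "split",
        "attribute": node.attribute,
        "default_value": node.default_value,
        "children": {v: tree_to_dict(c) for v, c in node.children.items()},
    }


def tree_from_dict(payload: Mapping) -> Node:
    if payload["kind"] == "leaf":
        return Leaf(
            payload["label"],
            payload.get("weight"),
            tuple((a, v) for a, v in payload.get("path", [])),
        )
    return Split(
        payload["attribute"],
        {v: tree_from_dict(c) for v, c in payload["children"].items()},
        payload.get("default_value", ""),
    )


def save_tree(tree: Node, path: str | Path) -> None:
    Path(path).write_text(json.dumps(tree_to_dict(tree), indent=2) + "\n")


def load_tree(path: str | Path) -> Node:
    return tree_from_dict(json.loads(Path(path).read_text()))


# ---------------------------------------------------------------------------
# tabular I/O for training examples


def examples_from_csv(path: str | Path, schema: AttributeSchema) -> list[LabeledExample]:
    """Read labeled examples from a CSV whose header is the attribute names
    plus a ``label`` column."""
    import pandas as pd

    frame = pd.read_csv(path, dtype=str)
    missing = set(schema.names) - set(frame.columns)
    if missing or "label" not in frame.columns:
        raise ValueError(f"CSV lacks required columns: {sorted(missing | {'label'} - set(frame.columns))}")
    return [
        LabeledExample({n: row[n] for n in schema.names}, row["label"])
        for row in frame.to_dict("records")
    ]


def examples_to_csv(examples: Sequence[LabeledExample], path: str | Path, schema: AttributeSchema) -> None:
    import pandas as pd

    rows = [
        {**{n: ex.assignment[n] for n in schema.names}, "label": ex.label}
        for ex in examples
    ]
    pd.DataFrame(rows).to_csv(path, index=False)
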