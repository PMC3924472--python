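"""Shipped defaults: attribute schema, training table and reference tree.

The deployed tool's concrete tree is not recoverable, so the default tree is
induced at run time from a fully enumerated training table labeled by a
transparent urgency rule:

* anything overdue or due today is a priority;
* anything due within the week is a priority only if somebody asked for it;
* everything else is not a priority.

The rule is deliberately area-independent — which life area a task belongs to
matters for quiz adaptation, not for whether the task is urgent — and is
plain configuration: any deployment can induce its own tree from its own
labeled table instead.
"""

from __future__ import annotations

import json
from importlib import resources

from .activity_model import Activity, AttributeSchema
from .decision_engine import (
    NON_PRIORITY,
    PRIORITY,
    LabeledExample,
    Node,
    assign_weights,
    induce_tree,
)

__all__ = [
    "default_schema",
    "default_rule",
    "default_training_table",
    "default_tree",
    "default_activity_bank",
]


def default_schema() -> AttributeSchema:
    """The attribute schema shipped as JSON configuration."""
    payload = json.loads(
        resources.files("taskbalance").joinpath("data/default_schema.json").read_text()
    )
    return AttributeSchema.from_dict(payload)


def default_rule(assignment: dict[str, str]) -> str:
    """Ground-truth labeling rule behind the shipped training table."""
    bucket = assignment.get("deadline_bucket")
    if bucket in ("overdue", "today"):
        return PRIORITY
    if bucket == "within_week" and assignment.get("requested_by") != "nobody":
        return PRIORITY
    return NON_PRIORITY


def default_training_table(schema: AttributeSchema | None = None) -> list[LabeledExample]:
    """Every point of the attribute grid labeled by :func:`default_rule`."""
    schema = schema or default_schema()
    return [LabeledExample(assignment, default_rule(assignment)) for assignment in schema.grid()]


def default_tree(schema: AttributeSchema | None = None) -> Node:
    """Weighted decision tree induced from the shipped training table."""
    schema = schema or default_schema()
    return assign_weights(induce_tree(default_training_table(schema), schema))


def default_activity_bank(schema: AttributeSchema | None = None) -> list[Activity]:
    """One activity per grid point — a bank that exercises every tree path.

    Ids encode the assignment so they are stable and self-describing.
    """
    schema = schema or default_schema()
    bank = []
    for assignment in schema.grid():
        ident = "-".join(assignment[name] for name in schema.names)
        bank.append(Activity(id=ident, name=ident.replace("-", " "), assignment=assignment))
    return bank
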