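import itertools
import math
from collections import Counter

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from taskbalance.activity_model import Activity, AttributeSchema
from taskbalance.decision_engine import (
    NON_PRIORITY,
    PRIORITY,
    LabeledExample,
    Leaf,
    Split,
    assign_weights,
    classify,
    entropy,
    induce_tree,
    information_gain,
    iter_leaves,
    load_tree,
    prioritise,
    save_tree,
)

from .conftest import make_activity

# ---------------------------------------------------------------------------
# independent greedy oracle: a from-scratch ID3 predictor used only in tests


def oracle_predict(examples, schema, assignment):
    """Predict a label by exhaustively recomputing gains at every node."""

    def H(labels):
        h = 0.0
        for c in Counter(labels).values():
            p = c / len(labels)
            h -= p * math.log2(p)
        return h

    def rec(exs, attrs, parent_major):
        if not exs:
            return parent_major
        labels = [label for _, label in exs]
        if len(set(labels)) == 1:
            return labels[0]
        major = (
            PRIORITY
            if labels.count(PRIORITY) >= labels.count(NON_PRIORITY)
            else NON_PRIORITY
        )
        if not attrs:
            return major
        base = H(labels)
        best, best_gain = None, -1.0
        for attr in sorted(attrs):
            remainder = 0.0
            for value in schema.domain(attr):
                sub = [label for ex, label in exs if ex[attr] == value]
                if sub:
                    remainder += len(sub) / len(exs) * H(sub)
            gain = base - remainder
            if gain > best_gain:
                best, best_gain = attr, gain
        branch = [e for e in exs if e[0][best] == assignment[best]]
        return rec(branch, [a for a in attrs if a != best], major)

    return rec(list(examples), list(schema.names), PRIORITY)


def random_table(rng):
    """A random small schema plus a random labeled table over it."""
    n_attrs = int(rng.integers(1, 6))
    attrs = tuple(
        (f"a{i}", tuple(f"v{j}" for j in range(int(rng.integers(2, 4)))))
        for i in range(n_attrs)
    )
    schema = AttributeSchema(attrs)
    n = int(rng.integers(1, 41))
    examples = []
    for _ in range(n):
        assignment = {
            name: domain[int(rng.integers(len(domain)))] for name, domain in attrs
        }
        label = PRIORITY if rng.random() < 0.5 else NON_PRIORITY
        examples.append(LabeledExample(assignment, label))
    return schema, examples


# ---------------------------------------------------------------------------
# entropy


class TestEntropy:
    @pytest.mark.parametrize(
        ("counts", "expected"),
        [
            ({PRIORITY: 4, NON_PRIORITY: 4}, 1.0),
            ({PRIORITY: 8, NON_PRIORITY: 0}, 0.0),
            ({PRIORITY: 8}, 0.0),
            # hand evaluation of -(1/4 log2 1/4 + 3/4 log2 3/4)
            ({PRIORITY: 1, NON_PRIORITY: 3}, 0.811278),
        ],
    )
    def test_closed_forms(self, counts, expected):
        assert entropy(counts) == pytest.approx(expected, abs=1e-6)

    def test_all_zero_counts_rejected(self):
        with pytest.raises(ValueError):
            entropy({PRIORITY: 0, NON_PRIORITY: 0})

    @given(
        counts=st.lists(st.integers(min_value=0, max_value=50), min_size=1, max_size=6)
    )
    @settings(max_examples=200, derandomize=True)
    def test_permutation_invariant_and_bounded(self, counts):
        """Entropy ignores label identity and never exceeds log2 of the support size."""
        if sum(counts) == 0:
            counts[0] = 1
        labels = {f"L{i}": c for i, c in enumerate(counts)}
        permuted = {f"L{i}": c for i, c in enumerate(reversed(counts))}
        assert entropy(labels) == pytest.approx(entropy(permuted), abs=1e-12)
        support = sum(1 for c in counts if c > 0)
        assert 0.0 <= entropy(labels) <= math.log2(support) + 1e-12

    def test_uniform_k_label_entropy_is_log2_k(self):
        for k in (2, 3, 4, 8):
            assert entropy({f"L{i}": 5 for i in range(k)}) == pytest.approx(
                math.log2(k)
            )


# ---------------------------------------------------------------------------
# information gain


class TestInformationGain:
    def fixture_examples(self):
        # 4 examples, 2 binary attributes: x predicts the label perfectly,
        # y is independent of it
        rows = [
            ({"x": "0", "y": "0"}, NON_PRIORITY),
            ({"x": "0", "y": "1"}, NON_PRIORITY),
            ({"x": "1", "y": "0"}, PRIORITY),
            ({"x": "1", "y": "1"}, PRIORITY),
        ]
        return [LabeledExample(a, l) for a, l in rows]

    def test_constant_attribute_has_zero_gain(self):
        examples = [
            LabeledExample({"x": "0"}, PRIORITY),
            LabeledExample({"x": "0"}, NON_PRIORITY),
        ]
        assert information_gain(examples, "x") == 0.0

    def test_perfect_predictor_gains_full_label_entropy(self):
        examples = self.fixture_examples()
        assert information_gain(examples, "x") == pytest.approx(1.0)
        assert information_gain(examples, "y") == pytest.approx(0.0)

    def test_matches_direct_partition_enumeration(self):
        """Gain equals base entropy minus the explicitly enumerated remainder."""
        rows = [
            ({"x": "0", "y": "0"}, PRIORITY),
            ({"x": "0", "y": "1"}, NON_PRIORITY),
            ({"x": "1", "y": "0"}, PRIORITY),
            ({"x": "1", "y": "1"}, PRIORITY),
        ]
        examples = [LabeledExample(a, l) for a, l in rows]
        # by hand: H(3,1) = 0.811278; splitting on x: branches (1P,1N) and (2P)
        # remainder = 1/2 * 1 + 1/2 * 0 = 0.5
        assert information_gain(examples, "x") == pytest.approx(0.811278 - 0.5, abs=1e-6)
        # splitting on y: branches (2P) and (1P,1N): same remainder by symmetry
        assert information_gain(examples, "y") == pytest.approx(0.811278 - 0.5, abs=1e-6)

    def test_unknown_attribute_rejected(self):
        with pytest.raises(KeyError):
            information_gain(self.fixture_examples(), "z")

    def test_nonnegative_on_random_tables(self, rng):
        for _ in range(50):
            schema, examples = random_table(rng)
            for attr in schema.names:
                assert information_gain(examples, attr) >= 0.0


# ---------------------------------------------------------------------------
# induction


class TestInduceTree:
    def test_single_perfect_attribute_gives_depth_one_tree(self):
        schema = AttributeSchema((("x", ("0", "1")), ("y", ("0", "1"))))
        rows = [
            ({"x": "0", "y": "0"}, NON_PRIORITY),
            ({"x": "0", "y": "1"}, NON_PRIORITY),
            ({"x": "1", "y": "0"}, PRIORITY),
            ({"x": "1", "y": "1"}, PRIORITY),
        ]
        tree = induce_tree([LabeledExample(a, l) for a, l in rows], schema)
        assert isinstance(tree, Split) and tree.attribute == "x"
        assert all(isinstance(c, Leaf) for c in tree.children.values())

    def test_pure_label_set_gives_single_leaf(self, schema):
        examples = [
            LabeledExample(make_activity(schema).assignment, PRIORITY)
            for _ in range(3)
        ]
        tree = induce_tree(examples, schema)
        assert isinstance(tree, Leaf) and tree.label == PRIORITY

    def test_conflicting_duplicates_resolve_to_majority(self):
        schema = AttributeSchema((("x", ("0", "1")),))
        examples = [
            LabeledExample({"x": "0"}, PRIORITY),
            LabeledExample({"x": "0"}, PRIORITY),
            LabeledExample({"x": "0"}, NON_PRIORITY),
        ]
        tree = induce_tree(examples, schema)
        assert classify(tree, {"x": "0"}).label == PRIORITY

    def test_empty_example_set_rejected(self, schema):
        with pytest.raises(ValueError):
            induce_tree([], schema)

    def test_matches_greedy_oracle_on_random_tables(self, rng):
        """Implementation and the exhaustive-gain oracle agree on the full grid."""
        for _ in range(60):
            schema, examples = random_table(rng)
            tree = induce_tree(examples, schema)
            pairs = [(dict(ex.assignment), ex.label) for ex in examples]
            for assignment in schema.grid():
                assert (
                    classify(tree, assignment).label
                    == oracle_predict(pairs, schema, assignment)
                )

    def test_resubstitution_accuracy_is_perfect_on_consistent_examples(self, rng):
        for _ in range(20):
            schema, _ = random_table(rng)
            # label by a deterministic rule of the assignment -> consistent
            def rule(a):
                return PRIORITY if sum(map(hash, a.values())) % 2 else NON_PRIORITY

            examples = [
                LabeledExample(g, rule(g))
                for g in itertools.islice(schema.grid(), 40)
            ]
            tree = induce_tree(examples, schema)
            assert all(
                classify(tree, ex.assignment).label == ex.label for ex in examples
            )


# ---------------------------------------------------------------------------
# weights


class TestAssignWeights:
    def test_single_leaf_gets_weight_one(self):
        weighted = assign_weights(Leaf(PRIORITY))
        assert weighted.weight == 1

    def test_two_leaf_deadline_tree_ranks_today_first(self, two_value_schema):
        examples = [
            LabeledExample({"deadline_bucket": "today"}, PRIORITY),
            LabeledExample({"deadline_bucket": "none"}, NON_PRIORITY),
        ]
        weighted = assign_weights(induce_tree(examples, two_value_schema))
        today = classify(weighted, {"deadline_bucket": "today"})
        none = classify(weighted, {"deadline_bucket": "none"})
        assert (today.label, today.weight) == (PRIORITY, 2)
        assert (none.label, none.weight) == (NON_PRIORITY, 1)

    def test_weights_are_a_permutation_on_random_trees(self, rng):
        for _ in range(25):
            schema, examples = random_table(rng)
            weighted = assign_weights(induce_tree(examples, schema))
            weights = sorted(leaf.weight for leaf in iter_leaves(weighted))
            assert weights == list(range(1, len(weights) + 1))

    def test_priority_leaves_outweigh_non_priority_leaves(self, tree):
        priority = [l.weight for l in iter_leaves(tree) if l.label == PRIORITY]
        non_priority = [l.weight for l in iter_leaves(tree) if l.label == NON_PRIORITY]
        assert min(priority) > max(non_priority)


# ---------------------------------------------------------------------------
# classification and prioritisation


class TestClassify:
    def test_two_leaf_tree_walk(self, two_value_schema):
        examples = [
            LabeledExample({"deadline_bucket": "today"}, PRIORITY),
            LabeledExample({"deadline_bucket": "none"}, NON_PRIORITY),
        ]
        weighted = assign_weights(induce_tree(examples, two_value_schema))
        result = classify(weighted, {"deadline_bucket": "today"})
        assert result.label == PRIORITY
        assert result.path == (("deadline_bucket", "today"),)
        assert not result.fallback_used

    def test_single_leaf_tree_labels_everything(self, schema):
        weighted = assign_weights(Leaf(NON_PRIORITY))
        assert classify(weighted, make_activity(schema)).label == NON_PRIORITY

    def test_out_of_schema_value_takes_fallback_branch(self, tree, schema):
        act = make_activity(schema, deadline_bucket="whenever")
        result = classify(tree, act)
        assert result.fallback_used
        assert result.label in (PRIORITY, NON_PRIORITY)


class TestPrioritise:
    def test_priority_label_beats_non_priority(self, tree, schema):
        a = make_activity(schema, "hw", deadline_bucket="today")
        b = make_activity(schema, "tv", deadline_bucket="none", requested_by="nobody")
        decision = prioritise(tree, a, b, schema)
        assert decision.winner == "hw"
        assert not decision.tie_break_used

    def test_same_label_resolved_by_greater_weight(self, tree, schema):
        a = make_activity(schema, "overdue-task", deadline_bucket="overdue")
        b = make_activity(schema, "today-task", deadline_bucket="today")
        decision = prioritise(tree, a, b, schema)
        assert decision.winner == "overdue-task"
        assert decision.tie_break_used
        assert decision.winner_weight > decision.loser_weight

    def test_identical_assignments_break_on_lexicographic_id(self, tree, schema):
        a = make_activity(schema, "zzz")
        b = make_activity(schema, "aaa")
        decision = prioritise(tree, a, b, schema)
        assert decision.winner == "aaa"
        assert decision.tie_break_used
        assert "lexicographically" in decision.rationale

    def test_invalid_activity_names_the_offender(self, tree, schema):
        bad = Activity("broken", "broken", {"area": "academic"})
        good = make_activity(schema, "ok")
        with pytest.raises(ValueError, match="broken"):
            prioritise(tree, bad, good, schema)

    def test_antisymmetric_and_total_over_the_full_grid(self, tree, schema, bank):
        """Swapping the pair swaps winner/loser; every validated pair resolves."""
        probe = bank[:: max(1, len(bank) // 12)]  # a spread of grid points
        for a in probe:
            for b in probe:
                d_ab = prioritise(tree, a, b, schema)
                d_ba = prioritise(tree, b, a, schema)
                assert d_ab.winner == d_ba.winner
                assert d_ab.loser == d_ba.loser


# ---------------------------------------------------------------------------
# serialisation


def test_tree_round_trips_through_json(tree, schema, bank, tmp_path):
    path = tmp_path / "tree.json"
    save_tree(tree, path)
    loaded = load_tree(path)
    for act in bank:
        original, reread = classify(tree, act), classify(loaded, act)
        assert (original.label, original.weight) == (reread.label, reread.weight)
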