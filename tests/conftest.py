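import numpy as np
import pytest

from taskbalance import defaults
from taskbalance.activity_model import Activity, AttributeSchema


@pytest.fixture(scope="session")
def schema() -> AttributeSchema:
    return defaults.default_schema()


@pytest.fixture(scope="session")
def tree(schema):
    return defaults.default_tree(schema)


@pytest.fixture(scope="session")
def bank(schema):
    return defaults.default_activity_bank(schema)


@pytest.fixture()
def rng():
    return np.random.default_rng(20130701)


def make_activity(schema, ident="act", **overrides) -> Activity:
    """A conforming activity with explicit attribute overrides."""
    assignment = {name: schema.domain(name)[0] for name in schema.names}
    assignment.update(overrides)
    return Activity(id=ident, name=ident, assignment=assignment)


@pytest.fixture(scope="session")
def two_value_schema() -> AttributeSchema:
    """Minimal schema whose deadline domain has just two buckets."""
    return AttributeSchema((("deadline_bucket", ("today", "none")),))
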