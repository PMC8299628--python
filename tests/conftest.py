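from __future__ import annotations

import random

import pytest

from starcif import FixtureSpec, generate_fixture
from starcif.fixtures import edge_case_corpus, random_specs


@pytest.fixture(scope="session")
def corpus():
    """Hand-written edge-case documents plus a band of generated fixtures:
    the shared tokenizer/reader test corpus (name, text) pairs."""
    docs = list(edge_case_corpus())
    for spec in random_specs(20, seed=99):
        docs.append((f"generated_{spec.seed}", generate_fixture(spec).text))
    return docs


@pytest.fixture(scope="session")
def fixture_family():
    """A modest family of generated fixtures with ground truth, reused by
    several suites."""
    return [generate_fixture(spec) for spec in random_specs(40, seed=7)]


@pytest.fixture()
def rng():
    return random.Random(2024)
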