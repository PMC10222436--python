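import numpy as np
import pytest

from casctriple.corpus import RelationSchema, annotate
from casctriple.synthetic import GeneratorConfig, default_schema, generate_corpus


@pytest.fixture
def rng():
    return np.random.default_rng(42)


@pytest.fixture(scope="session")
def schema4():
    return default_schema(4)


@pytest.fixture(scope="session")
def small_corpus(schema4):
    """100 sentences, mixed overlap classes, deterministic."""
    return generate_corpus(GeneratorConfig(n_sentences=100, seed=7), schema4)


@pytest.fixture
def toy_schema():
    return RelationSchema(("P0", "P1"))


@pytest.fixture
def toy_sentence(toy_schema):
    return annotate("abc", [{"subject": "a", "predicate": "P0", "object": "c"}],
                    toy_schema)
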