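import numpy as np
import pytest

from frsystem import (
    AggregatorSpec,
    InferenceConfig,
    KnowledgeSpec,
    NegationSpec,
    PrecedenceSpec,
    enumerate_knowledge_rules,
    knowledge_presets,
    load_default_config,
)


@pytest.fixture(scope="session")
def variables():
    return load_default_config()


@pytest.fixture(scope="session")
def enumerated_rules():
    return enumerate_knowledge_rules()


@pytest.fixture(scope="session")
def classic_config():
    return InferenceConfig(mode="classic")


@pytest.fixture(scope="session")
def k2_config():
    return knowledge_presets()["K2"]


@pytest.fixture(scope="session")
def max_knowledge():
    """The max-aggregator / standard-negation knowledge measure (closed form)."""
    return KnowledgeSpec(
        kind="prec_based",
        precedence=PrecedenceSpec(
            aggregator=AggregatorSpec(kind="sm"), negation=NegationSpec(kind="standard")
        ),
    )


@pytest.fixture(scope="session")
def unit_grid():
    return np.linspace(0.0, 1.0, 101)
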