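import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from adocnet import (
    DirectedNetwork,
    GeneratorConfig,
    NodeAttributeTable,
    generate_dataset,
)

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    max_examples=25,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


def make_random_network(n: int, p: float, seed: int) -> DirectedNetwork:
    rng = np.random.default_rng(seed)
    A = (rng.random((n, n)) < p).astype(np.uint8)
    np.fill_diagonal(A, 0)
    return DirectedNetwork.from_adjacency(A)


def make_random_attrs(n: int, seed: int, node_ids=None) -> NodeAttributeTable:
    rng = np.random.default_rng(seed)
    frame = pd.DataFrame(
        {
            "gender": rng.integers(0, 2, n),
            "experience": rng.integers(0, 2, n),
            "emotion_polarity": rng.integers(0, 3, n),
            "topic_preference": rng.integers(1, 8, n),
        },
        index=pd.Index(node_ids if node_ids is not None else range(n)),
    )
    return NodeAttributeTable(frame)


@pytest.fixture(scope="session")
def small_bundle():
    """A 60-user synthetic community shared by coding / IO / sweep tests."""
    return generate_dataset(GeneratorConfig(seed=2024, n_users=60))


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
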