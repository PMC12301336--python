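import numpy as np
import pytest

from synfuse.model import TrainConfig, train_model
from synfuse.ppi import WalkConfig, embed_network
from synfuse.synthetic import FixtureConfig, make_study


@pytest.fixture(scope="session")
def small_study():
    """A compact planted-rule study used across module tests."""
    return make_study(FixtureConfig(n_drugs=10, n_cell_lines=6, n_genes=30,
                                    n_triplets=150, noise=0.0, seed=1))


@pytest.fixture(scope="session")
def small_table(small_study):
    cfg = WalkConfig(seed=0, walks_per_node=5, walk_length=20, iterations=60)
    return embed_network(small_study.network, cfg)


@pytest.fixture(scope="session")
def trained_small(small_study, small_table):
    """A briefly trained full-variant model for prediction-level tests."""
    cfg = TrainConfig(epochs=4, patience=4, batch_size=64, seed=0)
    return train_model(small_study.triplets, small_study.expression.matrix,
                       small_table, cfg, "full")
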