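import numpy as np
import pytest

from spotguide import (
    SyntheticConfig,
    TrainConfig,
    build_knn_graph,
    generate_synthetic_st,
    preprocess,
)


@pytest.fixture(scope="session")
def tiny_fixture():
    """10x10 lattice, 3 planted bands, 60 genes: fast enough for unit tests."""
    dataset, marker_map = generate_synthetic_st(
        SyntheticConfig(grid_rows=10, grid_cols=10, n_domains=3, n_genes=60, seed=0)
    )
    return dataset, marker_map


@pytest.fixture(scope="session")
def tiny_graph(tiny_fixture):
    dataset, _ = tiny_fixture
    return build_knn_graph(dataset.coords, k=3)


@pytest.fixture(scope="session")
def tiny_X(tiny_fixture):
    dataset, _ = tiny_fixture
    X, _ = preprocess(dataset)
    return X


@pytest.fixture(scope="session")
def small_train_config():
    return TrainConfig(pretrain_epochs=40, finetune_max_epochs=60,
                       hidden_dim=32, embed_dim=16, classifier_hidden=8, seed=0)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
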