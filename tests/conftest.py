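import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # for oracles.py

from ucnbench import (
    GNNConfig,
    SeriesSpec,
    build_pairs,
    featurize,
    generate_series,
    parse_molecule,
    split_pairs,
    train,
)

# one-site scaffold used by small unit fixtures
ONE_SITE_SCAFFOLD = "O=C(N[*:1])c1ccc2nc(C)sc2c1"
TWO_SITE_SCAFFOLD = "O=C(N[*:1])c1cc([*:3])c2nc([*:2])sc2c1"


@pytest.fixture(scope="session")
def small_series():
    """Zero-noise 16-compound congeneric series with planted weights."""
    spec = SeriesSpec(
        scaffold_template=TWO_SITE_SCAFFOLD,
        substituent_library={
            1: [("C", 0.9), ("N", -0.6), ("O", 0.3), ("Cl", -1.1)],
            2: [("C", 0.5), ("O", -0.8)],
            3: [("F", 0.0), ("Br", 1.2)],
        },
        base_activity=7.0,
        noise_sd=0.0,
        n_compounds=16,
        seed=11,
        target_id="unit",
    )
    records, truth = generate_series(spec)
    return spec, records, truth


@pytest.fixture(scope="session")
def small_split(small_series):
    _, records, _ = small_series
    pairs = build_pairs(records, mcs_threshold=0.5, min_delta=1.0)
    return split_pairs(pairs, train_frac=0.8, seed=3)


@pytest.fixture(scope="session")
def trained_mse_model(small_split):
    cfg = GNNConfig(
        hidden_dim=16, n_message_passes=2, head_hidden=16,
        learning_rate=3e-3, epochs=40, batch_pairs=16, seed=5, loss_mode="mse",
    )
    return train(small_split, cfg)


@pytest.fixture(scope="session")
def trained_ucn_model(small_split):
    cfg = GNNConfig(
        hidden_dim=16, n_message_passes=2, head_hidden=16,
        learning_rate=3e-3, epochs=40, batch_pairs=16, seed=5, loss_mode="mse_ucn",
    )
    return train(small_split, cfg)


@pytest.fixture()
def benzene_graph():
    return featurize(parse_molecule("c1ccccc1"))


def make_linear_model(seed: int = 0, hidden_dim: int = 8, n_passes: int = 1) -> "TrainedGNN":
    """A GNN with identity activations: yhat is affine in the node features."""
    from ucnbench.model import TrainedGNN

    cfg = GNNConfig(
        hidden_dim=hidden_dim, n_message_passes=n_passes, head_hidden=hidden_dim,
        seed=seed, activation="identity",
    )
    return TrainedGNN(cfg)


@pytest.fixture()
def linear_model():
    return make_linear_model()
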