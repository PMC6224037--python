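"""Shared fixtures: all data are generated in-process, nothing is downloaded.

The heavier session-scoped fixtures (trained pan-allele models) are shared
between the unit tests and the acceptance suite to keep the run short.
"""

from __future__ import annotations

import numpy as np
import pytest

from mhcbench.pan import PanAlleleANN, PanModelConfig
from mhcbench.synth import (
    make_synthetic_alleles,
    pseudo_table,
    simulate_binding_data,
    simulate_elution_data,
)

# The pinned synthetic world for the pan-allele recovery checks: six alleles
# in two families of sizes (5, 1).  Family 0's first two members share an
# identical pseudo-sequence (a best-case neighbour pair for leave-one-out);
# the singleton family is an isolated allele with no near neighbour.
WORLD_SEED = 7
DATA_SEED = 8
SPLIT_SEED = 9


@pytest.fixture(scope="session")
def allele_world():
    return make_synthetic_alleles(6, 2, seed=WORLD_SEED, family_sizes=(5, 1))


@pytest.fixture(scope="session")
def binding_data(allele_world):
    return simulate_binding_data(allele_world, 2000, seed=DATA_SEED)


@pytest.fixture(scope="session")
def split_binding_data(binding_data):
    """Deterministic 80/20 train/test split of the pinned binding data."""
    rng = np.random.default_rng(SPLIT_SEED)
    idx = rng.permutation(len(binding_data))
    n_test = len(binding_data) // 5
    test = [binding_data[i] for i in idx[:n_test]]
    train = [binding_data[i] for i in idx[n_test:]]
    return train, test


@pytest.fixture(scope="session")
def pan_config():
    # 40 epochs: the training loss plateaus well before the 250-epoch
    # default on these fixtures; scaled down to keep the suite fast.
    return PanModelConfig(epochs=40, seed=0)


@pytest.fixture(scope="session")
def fitted_pan(allele_world, split_binding_data, pan_config):
    train, _ = split_binding_data
    return PanAlleleANN(train, pseudo_table(allele_world), pan_config).fit()


@pytest.fixture(scope="session")
def elution_world():
    """Two-allele world + trained model + proteome/repertoire for elution tests."""
    models = make_synthetic_alleles(2, 1, seed=WORLD_SEED)
    data = simulate_binding_data(models, 1500, seed=DATA_SEED)
    results = PanAlleleANN(
        data, pseudo_table(models), PanModelConfig(epochs=30, seed=0)
    ).fit()
    proteome, repertoire = simulate_elution_data(
        models, 50000, threshold_nm=500.0, seed=SPLIT_SEED
    )
    return models, results, proteome, repertoire
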