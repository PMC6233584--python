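import logging

import numpy as np
import pytest

from cellimp import CountMatrix, ImputerConfig, normalize, simulate_counts

logging.getLogger("cellimp").setLevel(logging.ERROR)
logging.getLogger("cellimp.dropout_adjust").setLevel(logging.ERROR)


@pytest.fixture
def tiny_counts() -> CountMatrix:
    """3 cells x 4 genes with a zero column and varied depths."""
    arr = np.array([
        [2, 0, 8, 0],
        [1, 3, 6, 0],
        [5, 5, 0, 0],
    ])
    return CountMatrix(arr, ["c1", "c2", "c3"], ["g1", "g2", "g3", "g4"])


@pytest.fixture(scope="session")
def two_cluster_data():
    """Small two-subpopulation dataset with planted dropouts."""
    return simulate_counts(
        n_cells=80, n_genes=400, n_subpops=2, seed=11,
        depth_range=(2e4, 6e4), logmean_spread=1.5,
        dropout_logistic_params=(0.5, -1.2),
    )


@pytest.fixture(scope="session")
def two_cluster_X(two_cluster_data):
    return normalize(two_cluster_data.counts, min_fitting_genes=100)


@pytest.fixture
def fast_config() -> ImputerConfig:
    return ImputerConfig(min_fitting_genes=100, preselect_genes=500, seed=5)
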