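import sys
from pathlib import Path

import numpy as np
import pytest
from hypothesis import settings

sys.path.insert(0, str(Path(__file__).parent))  # tests/reference.py oracles

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")

from bnetreg.data import ExpressionDataset, standardize
from bnetreg.graph import GeneNetwork, build_normalized_laplacian
from bnetreg.model import Hyperparameters, ModelState


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)


@pytest.fixture
def star_network():
    """Five genes, one hub connected to four satellites."""
    edges = [("g0", f"g{i}") for i in range(1, 5)]
    return GeneNetwork.from_edges(edges, nodes=[f"g{i}" for i in range(5)])


@pytest.fixture
def star_laplacian(star_network):
    return build_normalized_laplacian(star_network)


@pytest.fixture
def small_dataset(rng):
    """n=20, p=5 standardized Gaussian-response dataset."""
    n, p = 20, 5
    X, _, _ = standardize(rng.standard_normal((n, p)))
    beta = np.array([1.0, 0.5, 0.5, 0.0, 0.0])
    y = X @ beta + 0.5 * rng.standard_normal(n)
    return ExpressionDataset(
        X=X, y=y, gene_ids=[f"g{i}" for i in range(p)],
        sample_ids=[f"s{i}" for i in range(n)], standardized=True,
    )


@pytest.fixture
def valid_state(rng):
    return ModelState(
        beta=rng.normal(size=5), sigma2=0.8,
        tau2=rng.uniform(0.5, 2.0, size=5), r=1.3, lambda2=0.9,
    )


@pytest.fixture
def default_hp():
    return Hyperparameters()
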