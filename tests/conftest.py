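"""Shared fixtures: small random networks and partitions built at test time."""

import numpy as np
import pytest

from mesoscope import Partition, WeightedNetwork


def make_random_network(rng, n=8, density=0.5, directed=False):
    """Random weighted network with approximately the given density."""
    mat = np.where(rng.random((n, n)) < density, rng.gamma(2.0, 1.0, (n, n)), 0.0)
    np.fill_diagonal(mat, 0.0)
    if not directed:
        mat = np.triu(mat, k=1)
        mat = mat + mat.T
    if not (mat > 0).any():  # ensure at least one edge
        mat[0, 1] = mat[1, 0] = 1.0
    return WeightedNetwork(mat, directed=directed)


def make_random_partition(rng, n, K):
    """Random partition guaranteed to use all K labels."""
    labels = rng.integers(1, K + 1, size=n)
    labels[:K] = np.arange(1, K + 1)
    return Partition(labels)


@pytest.fixture
def rng():
    return np.random.default_rng(20240915)


@pytest.fixture
def random_network(rng):
    return make_random_network(rng)


@pytest.fixture(scope="session")
def planted_assortative():
    from mesoscope import motif_preset, sample_planted_network

    return sample_planted_network(motif_preset("assortative"), seed=11)


@pytest.fixture(scope="session")
def planted_core_periphery():
    from mesoscope import motif_preset, sample_planted_network

    return sample_planted_network(motif_preset("core_periphery"), seed=11)
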