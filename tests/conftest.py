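"""Shared fixtures: small weighted networks and matrix builders."""

import numpy as np
import pytest

from conncrit import ConnectivityMatrix, ThresholdedNetwork, binarize


def make_matrix(weights, subject_id="fixture"):
    """ConnectivityMatrix from a dense array or upper-triangle dict {(i,j): w}."""
    if isinstance(weights, dict):
        n = max(max(i, j) for i, j in weights) + 1
        w = np.zeros((n, n))
        for (i, j), v in weights.items():
            w[i, j] = w[j, i] = v
        weights = w
    return ConnectivityMatrix(subject_id=subject_id, weights=np.asarray(weights, float))


def make_network(weights, w_t) -> ThresholdedNetwork:
    return binarize(make_matrix(weights), w_t)


def random_symmetric(n, rng, scale=1.0):
    """Random symmetric matrix with entries in [-scale, scale], zero diagonal."""
    w = rng.uniform(-scale, scale, size=(n, n))
    w = (w + w.T) / 2
    np.fill_diagonal(w, 0.0)
    return w


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def relay_network():
    """Two nodes, one strong edge: node 2 deterministically relays node 1."""
    return make_network({(0, 1): 0.9}, 0.5)


@pytest.fixture
def cancellation_network():
    """Hub node 2 receives +0.6 and -0.6; simultaneous inputs cancel."""
    return make_network({(0, 2): 0.6, (1, 2): -0.6}, 0.5)
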