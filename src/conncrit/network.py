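"""Thresholding of weighted connectomes and topology measures of the sweep.

The cut-off threshold is ``w_t = <|w|> + n * sigma_|w|`` with mean and
population standard deviation taken over the N(N-1)/2 upper-triangle
off-diagonal magnitudes of one subject's matrix; sweeping the multiplier
``n`` traces the percolation and clustering phase transitions.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components

from .errors import ParameterError
from .io import ConnectivityMatrix

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ThresholdSpec:
    """Cut-off threshold ``w_t = mean_abs_w + n * sd_abs_w`` for one matrix."""

    n: float
    mean_abs_w: float
    sd_abs_w: float

    @property
    def w_t(self) -> float:
        return self.mean_abs_w + self.n * self.sd_abs_w


@dataclass(frozen=True)
class ThresholdedNetwork:
    """Binary adjacency ``a_ij = [|w_ij| > w_t]`` with the retained signed weights."""

    adjacency: np.ndarray = field(repr=False)
    retained_weights: np.ndarray = field(repr=False)
    w_t: float = 0.0

    @property
    def n_nodes(self) -> int:
        return self.adjacency.shape[0]


@dataclass(frozen=True)
class TopologySummary:
    lcc_fraction: float
    clustering: float
    delta_clustering: float = float("nan")


def compute_threshold(matrix: ConnectivityMatrix, n: float) -> ThresholdSpec:
    """Mean-plus-n-sigma threshold over the off-diagonal ``|w|`` values.

    The standard deviation is the population one (ddof=0) so threshold
    values are reproducible and independent of estimator convention.
    """
    vals = matrix.offdiag_abs()
    mean = float(vals.mean())
    sd = float(vals.std(ddof=0))
    if sd == 0.0:
        logger.warning(
            "subject %s: all off-diagonal |w| identical; threshold degenerates to the mean",
            matrix.subject_id,
        )
    return ThresholdSpec(n=float(n), mean_abs_w=mean, sd_abs_w=sd)


def binarize(matrix: ConnectivityMatrix, w_t: float) -> ThresholdedNetwork:
    """Keep edges with ``|w_ij| > w_t`` (strict), preserving the weight sign.

    Negative correlations survive by magnitude: anti-correlated regions
    are as informative for signal transfer as correlated ones.
    """
    if w_t < 0:
        raise ParameterError("w_t must be nonnegative (clamp Eq.-style thresholds at 0)")
    adj = (np.abs(matrix.weights) > w_t).astype(np.int8)
    np.fill_diagonal(adj, 0)
    retained = np.where(adj == 1, matrix.weights, 0.0)
    return ThresholdedNetwork(adjacency=adj, retained_weights=retained, w_t=float(w_t))


def largest_component_fraction(network: ThresholdedNetwork) -> float:
    """Size of the largest connected component divided by N.

    Isolated nodes count as size-1 components and remain in the
    normalization, so the value lies in [1/N, 1].
    """
    n = network.n_nodes
    n_comp, labels = connected_components(
        csr_matrix(network.adjacency), directed=False
    )
    largest = int(np.bincount(labels, minlength=n_comp).max())
    return largest / n


def clustering_coefficient(network: ThresholdedNetwork) -> float:
    """Global transitivity: 3 * triangles / connected triples.

    Computed as ``trace(A^3) / sum_v d_v (d_v - 1)``; returns 0 when the
    graph has no connected triples (e.g. no edges or a perfect matching).
    """
    a = network.adjacency.astype(float)
    deg = a.sum(axis=1)
    triples = float((deg * (deg - 1)).sum())
    if triples == 0.0:
        return 0.0
    closed = float(np.trace(a @ a @ a))  # = 6 * triangles
    return closed / triples


def delta_clustering(
    c_series: list[tuple[float, float]]
) -> list[tuple[float, float]]:
    """Successive clustering drops ``dC(i) = C(i) - C(i+1)`` along a threshold sweep.

    ``c_series`` is an ordered sequence of (n, C) pairs with strictly
    increasing n, indexed from the smallest threshold; the result has one
    fewer element and telescopes to ``C(first) - C(last)``.
    """
    if len(c_series) < 2:
        raise ParameterError("delta_clustering needs at least 2 points")
    ns = [n for n, _ in c_series]
    if any(b <= a for a, b in zip(ns, ns[1:])):
        raise ParameterError("c_series must be ordered by strictly increasing n")
    return [
        (c_series[i][0], c_series[i][1] - c_series[i + 1][1])
        for i in range(len(c_series) - 1)
    ]
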