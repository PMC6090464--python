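"""Mutual-information readout of the signal-transfer simulation.

For every ordered region pair (i, j) the transfer score is the plug-in
mutual information ``m(i,j) = H(s_i) + H(r_j) - H(s_i, r_j)`` in nats,
computed from the (empirical or exact) joint distribution of the ternary
stimulus state at i and response state at j.  Scores are averaged per
receiving node over all N-1 possible senders, ``<m(j)> = sum_i m(i,j) /
(N-1)``, and over nodes to the network score ``m = sum_j <m(j)> / N``.

Marginals are always taken from the same joint table, so the plug-in
estimate is internally consistent and nonnegative by construction; no
entropy bias correction is applied (comparisons across thresholds are
relative, and the same estimator is used in every cell).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import ParameterError, ValidationError
from .network import ThresholdedNetwork
from .synthetic import generate_signals
from .transfer import _state_index, exact_joint_tables, propagate

_PROB_TOL = 1e-9


@dataclass(frozen=True)
class MutualInfoResult:
    """Pairwise, per-node, and network-averaged mutual information (nats)."""

    pairwise: np.ndarray = field(repr=False)
    per_node: np.ndarray = field(repr=False)
    network_mean: float = 0.0
    n_trials: int = 0
    p: float = 0.0
    w_t: float = 0.0
    seed: int | None = None


def _xlogx(p: np.ndarray) -> np.ndarray:
    """``p * ln p`` with the convention 0 ln 0 = 0."""
    out = np.zeros_like(p)
    nz = p > 0
    out[nz] = p[nz] * np.log(p[nz])
    return out


def entropy(prob_table: np.ndarray) -> float:
    """Shannon entropy ``-sum p ln p`` in nats of a finite probability table."""
    p = np.asarray(prob_table, dtype=float)
    if np.any(p < -_PROB_TOL):
        raise ValidationError("probability table has negative mass")
    total = float(p.sum())
    if abs(total - 1.0) > _PROB_TOL:
        raise ValidationError(f"probability table sums to {total}, not 1")
    return float(-_xlogx(np.clip(p, 0.0, None)).sum())


def pairwise_mutual_information(joint: np.ndarray) -> float:
    """``m = H(row marginal) + H(column marginal) - H(joint)`` in nats."""
    j = np.asarray(joint, dtype=float)
    h_joint = entropy(j)
    h_row = entropy(j.sum(axis=1))
    h_col = entropy(j.sum(axis=0))
    return max(0.0, h_row + h_col - h_joint)


def _mi_from_joint_tables(joints: np.ndarray) -> tuple[np.ndarray, np.ndarray, float]:
    """Vectorized Eq.-style averaging over an (N, N, 3, 3) joint array."""
    n = joints.shape[0]
    h_joint = -_xlogx(joints).sum(axis=(2, 3))
    h_s = -_xlogx(joints.sum(axis=3)).sum(axis=2)  # H(s_i) per (i, j)
    h_r = -_xlogx(joints.sum(axis=2)).sum(axis=2)  # H(r_j) per (i, j)
    pairwise = np.clip(h_s + h_r - h_joint, 0.0, None)
    np.fill_diagonal(pairwise, 0.0)
    per_node = pairwise.sum(axis=0) / (n - 1)
    return pairwise, per_node, float(per_node.mean())


def estimate_network_mi(
    network: ThresholdedNetwork, p: float, n_trials: int = 1000, seed: int = 0
) -> MutualInfoResult:
    """Monte-Carlo mutual information under activation density ``p``.

    Draws ``n_trials`` ternary stimulus vectors, propagates each through
    the network in one synchronous step, and accumulates empirical 3x3
    joint frequencies for every ordered pair.
    """
    if not 0.0 < p < 0.5:
        raise ParameterError(f"p must be in (0, 0.5), got {p}")
    if n_trials < 1:
        raise ParameterError("n_trials must be positive")
    n = network.n_nodes
    stimuli = generate_signals(n, p, n_trials, seed)
    responses = propagate(network, stimuli).states
    s_idx = _state_index(stimuli)
    r_idx = _state_index(responses)
    joints = np.empty((n, n, 3, 3))
    for a in range(3):
        sa = (s_idx == a).astype(float)
        for b in range(3):
            rb = (r_idx == b).astype(float)
            joints[:, :, a, b] = sa.T @ rb
    joints /= n_trials
    pairwise, per_node, mean = _mi_from_joint_tables(joints)
    return MutualInfoResult(
        pairwise=pairwise,
        per_node=per_node,
        network_mean=mean,
        n_trials=n_trials,
        p=p,
        w_t=network.w_t,
        seed=seed,
    )


def exact_network_mi(network: ThresholdedNetwork, p: float) -> MutualInfoResult:
    """Deterministic mutual information via exact enumeration of stimuli.

    Same averaging contract as :func:`estimate_network_mi` but with the
    exact joint tables; only feasible for small N (3^N configurations).
    """
    joints = exact_joint_tables(network, p)
    pairwise, per_node, mean = _mi_from_joint_tables(joints)
    return MutualInfoResult(
        pairwise=pairwise,
        per_node=per_node,
        network_mean=mean,
        n_trials=0,
        p=p,
        w_t=network.w_t,
        seed=None,
    )
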