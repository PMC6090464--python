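"""One-step ternary signal propagation on a thresholded connectome.

Each node receives the summed weighted input of its retained neighbors,
``drive_j = sum_i a_ij w_ij s_i``, and responds +1 if the drive exceeds
the cut-off threshold, -1 if it falls below its negative, and 0 when the
drive magnitude is at or below the threshold.  The map is a single
synchronous stimulus-to-response step; no recurrent iteration or
avalanche dynamics.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import CapacityError, ParameterError
from .network import ThresholdedNetwork

#: states of the ternary alphabet in the canonical order used by joint tables
STATES = (1, -1, 0)

#: default exact-enumeration limit: 3^10 = 59,049 configurations
ENUMERATION_LIMIT = 10


@dataclass(frozen=True)
class ResponseVector:
    states: np.ndarray = field(repr=False)
    drive: np.ndarray = field(repr=False)


def _threshold_drive(drive: np.ndarray, w_t: float) -> np.ndarray:
    states = np.zeros_like(drive, dtype=np.int8)
    states[drive > w_t] = 1
    states[drive < -w_t] = -1
    return states


def propagate(
    network: ThresholdedNetwork, stimulus: np.ndarray
) -> ResponseVector:
    """Propagate one stimulus vector (or a batch) through the network.

    ``stimulus`` is a length-N ternary vector or an ``(T, N)`` batch over
    {-1, 0, +1}.  A drive magnitude exactly equal to the threshold maps
    to the 0 state (the inactive band is closed).
    """
    s = np.asarray(stimulus)
    n = network.n_nodes
    if s.shape[-1] != n:
        raise ParameterError(
            f"stimulus length {s.shape[-1]} does not match network size {n}"
        )
    drive = s.astype(float) @ network.retained_weights
    return ResponseVector(states=_threshold_drive(drive, network.w_t), drive=drive)


def _all_configurations(n: int) -> np.ndarray:
    """All 3^n ternary vectors over {1, -1, 0}, shape (3^n, n)."""
    grids = np.meshgrid(*([np.array(STATES, dtype=np.int8)] * n), indexing="ij")
    return np.stack([g.ravel() for g in grids], axis=-1)


def _configuration_probabilities(configs: np.ndarray, p: float) -> np.ndarray:
    """Product probability of each configuration under P(+1)=P(-1)=p."""
    n_active = np.count_nonzero(configs, axis=1)
    n = configs.shape[1]
    return p ** n_active * (1.0 - 2.0 * p) ** (n - n_active)


def _state_index(x: np.ndarray) -> np.ndarray:
    """Map {1, -1, 0} to table indices {0, 1, 2}."""
    return np.where(x == 1, 0, np.where(x == -1, 1, 2))


def exact_joint_tables(network: ThresholdedNetwork, p: float) -> np.ndarray:
    """Exact joint distributions P(s_i, r_j) for every ordered pair.

    Enumerates all 3^N stimulus configurations with their product
    probabilities and accumulates the exact joint mass.  Returns an
    ``(N, N, 3, 3)`` array indexed by (i, j, s-state, r-state) with the
    state order (+1, -1, 0); each 3x3 table sums to 1.
    """
    if not 0.0 < p < 0.5:
        raise ParameterError(f"p must be in (0, 0.5), got {p}")
    n = network.n_nodes
    if n > ENUMERATION_LIMIT:
        raise CapacityError(
            f"exact enumeration limited to N <= {ENUMERATION_LIMIT} "
            f"(3^{n} configurations); use the Monte-Carlo estimator instead"
        )
    configs = _all_configurations(n)
    probs = _configuration_probabilities(configs, p)
    responses = propagate(network, configs).states
    s_idx = _state_index(configs)  # (M, N)
    r_idx = _state_index(responses)  # (M, N)
    joint = np.zeros((n, n, 3, 3))
    for a in range(3):
        sa = np.where(s_idx == a, 1.0, 0.0) * probs[:, None]  # (M, N)
        for b in range(3):
            rb = np.where(r_idx == b, 1.0, 0.0)  # (M, N)
            joint[:, :, a, b] = sa.T @ rb
    return joint


def enumerate_exact_joint(
    network: ThresholdedNetwork, p: float, i: int, j: int
) -> np.ndarray:
    """Exact 3x3 joint probability table of (s_i, r_j) by full enumeration."""
    return exact_joint_tables(network, p)[i, j]
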