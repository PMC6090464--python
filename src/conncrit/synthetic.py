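"""Synthetic connectivity ensembles and ternary stimulus vectors.

The generator emulates the statistical structure the sweep analysis
assumes of resting-state functional connectomes, as a signal-plus-noise
model:

* a modular strong-edge core: nodes are partitioned into modules (two
  hemising blocks by default) and within-module edge magnitudes are the
  upper tail of the boundary-power law
  ``p(|w|) = (gamma+1) (1-|w|)^gamma`` — a power law in the reflected
  variable ``1-|w|`` adapted to the bounded correlation range;
* a measurement-noise floor: between-module magnitudes are weak,
  featureless values, uniform on (0, b) — the maximum-entropy choice
  for a noise band with no characteristic scale — with b calibrated so
  that the pooled magnitudes still yield the nominal exponent under a
  global boundary-power maximum-likelihood fit;
* hub structure: the strongest within-module weights are biased toward
  a nested core, and inter-module bridges concentrate on the hub cores
  (rich-club-like bridging), so cross edges close triangles through the
  module cliques;
* signed weights, symmetric matrices, zero diagonal, and a per-subject
  Gaussian perturbation standing in for inter-individual variability.

Sweeping the cut-off threshold upward therefore (i) strips the noise
floor, (ii) disconnects the modules exactly when the floor dies (a sharp
largest-component percolation transition), and (iii) then dissolves the
module cores (transitivity drop), with the surviving magnitudes above
the transition following the boundary-power model — the joint
phenomenology the threshold-sweep pipeline is designed to detect.

All randomness flows from a single integer seed through
``numpy.random.SeedSequence(seed, spawn_key)`` with fixed spawn keys per
stage, so every downstream figure analogue is exactly reproducible.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import optimize

from .errors import ParameterError
from .io import ConnectivityMatrix

logger = logging.getLogger(__name__)

# spawn keys of the per-stage random streams
_KEY_MAGNITUDES, _KEY_SIGNS, _KEY_PLACEMENT, _KEY_NOISE = range(4)


@dataclass(frozen=True)
class EnsembleSpec:
    """Parameters of a synthetic connectome ensemble.

    Parameters
    ----------
    n_regions:
        Number of brain regions N (nodes).
    n_subjects:
        Number of matrices in the ensemble.
    gamma:
        Boundary-power exponent of the strong-edge magnitude
        distribution; must exceed -1 for normalizability.
    n_modules:
        Number of disjoint modules in the strong-edge core.  Between-
        module pairs carry the uniform noise floor, whose width is
        calibrated automatically so the pooled magnitudes recover
        ``gamma`` under a global boundary-power ML fit.
    core_order_strength:
        In [0, 1]: how strongly within-module magnitudes are ordered
        toward a nested hub core (0 = random placement, 1 = strict
        onion ordering).
    bridge_order_strength:
        In [0, 1]: how strongly inter-module noise-floor edges
        concentrate on the hub cores (rich-club-like bridging).
    noise_sd:
        Standard deviation of the per-subject Gaussian perturbation of
        the signed weights (correlation units).
    seed:
        Master seed of the ensemble.
    """

    n_regions: int = 100
    n_subjects: int = 20
    gamma: float = 10.0
    n_modules: int = 2
    core_order_strength: float = 0.4
    bridge_order_strength: float = 1.0
    noise_sd: float = 0.005
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_regions < 4:
            raise ParameterError("n_regions must be >= 4")
        if self.n_subjects < 1:
            raise ParameterError("n_subjects must be >= 1")
        if self.gamma <= -1:
            raise ParameterError("gamma must be > -1 for a normalizable density")
        if self.n_modules < 2 or self.n_modules > self.n_regions // 2:
            raise ParameterError("n_modules must be in [2, n_regions // 2]")
        for name in ("core_order_strength", "bridge_order_strength"):
            if not 0.0 <= getattr(self, name) <= 1.0:
                raise ParameterError(f"{name} must be in [0, 1]")
        if self.noise_sd < 0.0:
            raise ParameterError("noise_sd must be nonnegative")


def boundary_power_ppf(u: np.ndarray | float, gamma: float) -> np.ndarray | float:
    """Inverse CDF of the boundary-power law: ``x = 1 - (1-u)^{1/(gamma+1)}``."""
    if gamma <= -1:
        raise ParameterError("gamma must be > -1")
    return 1.0 - (1.0 - np.asarray(u, dtype=float)) ** (1.0 / (gamma + 1.0))


def boundary_power_cdf(x: np.ndarray | float, gamma: float) -> np.ndarray | float:
    """CDF ``F(x) = 1 - (1-x)^{gamma+1}`` on [0, 1]."""
    if gamma <= -1:
        raise ParameterError("gamma must be > -1")
    return 1.0 - (1.0 - np.asarray(x, dtype=float)) ** (gamma + 1.0)


def sample_boundary_power(gamma: float, count: int, seed: int) -> np.ndarray:
    """Draw ``count`` magnitudes in [0, 1] from the boundary-power law.

    Uses inverse-CDF sampling of ``p(x) = (gamma+1)(1-x)^gamma``.
    """
    if count <= 0:
        raise ParameterError("count must be positive")
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    u = rng.random(count)
    return np.asarray(boundary_power_ppf(u, gamma))


def calibrated_noise_floor_width(gamma: float, tail_fraction: float) -> float:
    """Width b of the uniform noise floor that preserves the exponent.

    The global boundary-power MLE depends on the sample only through
    ``E[-ln(1-|w|)]``; b is chosen so the pooled mixture of the upper
    boundary-power tail (mass ``tail_fraction``) and a Uniform(0, b)
    floor matches the pure model's value ``1/(gamma+1)``, keeping the
    whole-matrix exponent estimate at its nominal value.
    """
    w_q = 1.0 - tail_fraction ** (1.0 / (gamma + 1.0))
    e_tail = -np.log(1.0 - w_q) + 1.0 / (gamma + 1.0)
    target = (1.0 / (gamma + 1.0) - tail_fraction * e_tail) / (1.0 - tail_fraction)
    if target <= 0:
        raise ParameterError(
            "no noise-floor width can preserve the exponent for this tail fraction"
        )

    def e_floor(b: float) -> float:
        # E[-ln(1-X)] for X ~ Uniform(0, b)
        return -((1.0 - b) * (1.0 - np.log1p(-b)) - 1.0) / b

    return float(optimize.brentq(lambda b: e_floor(b) - target, 1e-9, 0.999))


def _module_labels(n: int, k: int) -> tuple[np.ndarray, np.ndarray]:
    """Contiguous near-equal module labels and within-module depth (0 = hub)."""
    sizes = [n // k + (1 if i < n % k else 0) for i in range(k)]
    labels = np.repeat(np.arange(k), sizes)
    starts = np.cumsum([0] + sizes[:-1])
    depth = np.arange(n) - starts[labels]
    return labels, depth.astype(float)


def _rank_place(
    slots: np.ndarray,
    values: np.ndarray,
    pair_depth: np.ndarray,
    strength: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """Assign sorted values to slots by a blend of hub-depth and random order."""
    z = -(pair_depth - pair_depth.mean()) / (pair_depth.std() + 1e-12)
    score = strength * z + (1.0 - strength) * rng.normal(size=slots.size)
    out = np.empty(slots.size)
    out[np.argsort(score)[::-1]] = np.sort(values)[::-1]
    return out


def _base_matrix(spec: EnsembleSpec) -> np.ndarray:
    """Signed base weight matrix shared by all subjects (before noise)."""
    n = spec.n_regions
    iu, ju = np.triu_indices(n, k=1)
    n_pairs = iu.size
    labels, depth = _module_labels(n, spec.n_modules)
    intra = labels[iu] == labels[ju]
    n_intra = int(intra.sum())
    tail_fraction = n_intra / n_pairs

    rng_mag = np.random.default_rng(
        np.random.SeedSequence(spec.seed, spawn_key=(_KEY_MAGNITUDES,))
    )
    # within-module magnitudes: upper tail of the boundary-power law
    w_q = 1.0 - tail_fraction ** (1.0 / (spec.gamma + 1.0))
    u = rng_mag.random(n_intra)
    tail = 1.0 - (1.0 - w_q) * (1.0 - u) ** (1.0 / (spec.gamma + 1.0))
    # between-module magnitudes: calibrated uniform noise floor
    b = calibrated_noise_floor_width(spec.gamma, tail_fraction)
    floor = rng_mag.uniform(0.0, b, n_pairs - n_intra)

    rng_place = np.random.default_rng(
        np.random.SeedSequence(spec.seed, spawn_key=(_KEY_PLACEMENT,))
    )
    pair_depth = np.maximum(depth[iu], depth[ju])
    assignment = np.empty(n_pairs)
    ii = np.flatnonzero(intra)
    xx = np.flatnonzero(~intra)
    assignment[ii] = _rank_place(
        ii, tail, pair_depth[ii], spec.core_order_strength, rng_place
    )
    assignment[xx] = _rank_place(
        xx, floor, pair_depth[xx], spec.bridge_order_strength, rng_place
    )

    rng_sign = np.random.default_rng(
        np.random.SeedSequence(spec.seed, spawn_key=(_KEY_SIGNS,))
    )
    signs = rng_sign.choice([-1.0, 1.0], size=n_pairs)

    w = np.zeros((n, n))
    w[iu, ju] = assignment * signs
    return w + w.T


def generate_ensemble(spec: EnsembleSpec) -> list[ConnectivityMatrix]:
    """Generate the synthetic subject ensemble.

    A single base matrix (module structure, magnitudes, signs, hub
    placement) is drawn from the seed and shared across subjects; each
    subject adds an independent zero-mean Gaussian perturbation of scale
    ``noise_sd``, after which weights are clamped to [-1, 1],
    symmetrized, and the diagonal zeroed.  With ``noise_sd = 0`` all
    subjects are identical.
    """
    base = _base_matrix(spec)
    n = spec.n_regions
    iu, ju = np.triu_indices(n, k=1)
    rng_noise = np.random.default_rng(
        np.random.SeedSequence(spec.seed, spawn_key=(_KEY_NOISE,))
    )
    out = []
    clamped_total = 0
    for s in range(spec.n_subjects):
        w = base.copy()
        if spec.noise_sd > 0:
            eps = rng_noise.normal(0.0, spec.noise_sd, size=iu.size)
            w[iu, ju] += eps
            w[ju, iu] = w[iu, ju]
        clamped_total += int(np.count_nonzero(np.abs(w) > 1.0))
        np.clip(w, -1.0, 1.0, out=w)
        np.fill_diagonal(w, 0.0)
        out.append(ConnectivityMatrix(subject_id=f"synthetic_{s:04d}", weights=w))
    if clamped_total:
        logger.info("generate_ensemble: clamped %d weights to [-1, 1]", clamped_total)
    return out


def generate_signals(
    n_regions: int, p: float, n_trials: int, seed: int
) -> np.ndarray:
    """Draw ternary stimulus vectors, shape ``(n_trials, n_regions)``.

    Each entry is independently +1 with probability ``p``, -1 with
    probability ``p``, and 0 otherwise (symmetric activation density).
    """
    if not 0.0 < p < 0.5:
        raise ParameterError(f"activation density p must be in (0, 0.5), got {p}")
    if n_regions < 1 or n_trials < 1:
        raise ParameterError("n_regions and n_trials must be positive")
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    u = rng.random((n_trials, n_regions))
    return np.where(u < p, 1, np.where(u < 2 * p, -1, 0)).astype(np.int8)
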